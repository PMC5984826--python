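"""Partitioning homologous domains into structure-and-sequence subgroups.

Domain entries of a family database can be structurally heterogeneous (the
mutual C-alpha RMSD between members of one entry can exceed 10 A), which
makes a single profile built from the entry unrepresentative.  This module
splits the domains of a parent entry into subgroups whose members are
mutually similar: every member pair must satisfy

    C-alpha RMSD < rmsd_max  (default 7 A)   and
    sequence similarity > sim_min (default 10 percent identity).

The subgroup then replaces the parent entry as the database unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .interactions import InteractionVector

__all__ = ["DomainRecord", "Subgroup", "kabsch_rmsd", "pair_similarity",
           "align_pair", "domain_rmsd", "partition_subgroups"]

#: Minimum usable aligned C-alpha correspondences; below this a pair is
#: treated as structurally dissimilar.
MIN_CORRESPONDENCE = 20


@dataclass
class DomainRecord:
    """One annotated domain: sequence, C-alpha trace and site annotations."""

    id: str
    sequence: str
    ca_coords: np.ndarray | None = None  # (L, 3), NaN rows for absent positions
    site_positions: set[int] = field(default_factory=set)
    site_vectors: dict[int, InteractionVector] = field(default_factory=dict)
    parent_entry: str = ""

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if any(not 1 <= p <= L for p in self.site_positions):
            raise ValueError(f"domain {self.id}: site position outside 1..{L}")
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, float)
            if self.ca_coords.shape != (L, 3):
                raise ValueError(f"domain {self.id}: ca_coords not index-aligned with sequence")


@dataclass
class Subgroup:
    members: list[str]
    provenance: str = ""


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_pair(seq_a: str, seq_b: str):
    """Best global alignment (BLOSUM62, affine gaps) of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # BLOSUM62 has no 'X' column pairings beyond X itself; it does include X
    return _aligner().align(seq_a, seq_b)[0]


def pair_similarity(seq_a: str, seq_b: str) -> float:
    """Percent identity over the columns of a global alignment, in [0, 100]."""
    aln = align_pair(seq_a, seq_b)
    counts = aln.counts()
    length = aln.length
    return 100.0 * counts.identities / length if length else 0.0


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                correspondence: list[tuple[int, int]]) -> float:
    """Least-squares superposition RMSD over corresponding C-alpha pairs.

    The optimal rotation and translation (Kabsch) are removed before the
    root-mean-square deviation is taken.

    Parameters
    ----------
    coords_a, coords_b : (N, 3) arrays
    correspondence : list of (index_a, index_b) pairs, at least 3
    """
    if len(correspondence) < 3:
        raise ValueError("insufficient correspondence: need at least 3 aligned pairs")
    A = np.asarray([coords_a[i] for i, _ in correspondence], float)
    B = np.asarray([coords_b[j] for _, j in correspondence], float)
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("non-finite coordinates in correspondence")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ A.T).T - B
    return float(np.sqrt((diff ** 2).sum() / len(correspondence)))


def domain_rmsd(a: DomainRecord, b: DomainRecord) -> float:
    """C-alpha RMSD of two domains over their sequence-aligned positions.

    The correspondence comes from the pairwise global alignment (aligned,
    non-gap, C-alpha-bearing positions).  Pairs with fewer than
    ``MIN_CORRESPONDENCE`` usable positions return ``inf`` (dissimilar).
    """
    if a.ca_coords is None or b.ca_coords is None:
        return float("inf")
    aln = align_pair(a.sequence, b.sequence)
    corr = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            if np.isfinite(a.ca_coords[i]).all() and np.isfinite(b.ca_coords[j]).all():
                corr.append((i, j))
    if len(corr) < MIN_CORRESPONDENCE:
        return float("inf")
    return kabsch_rmsd(a.ca_coords, b.ca_coords, corr)


def partition_subgroups(domains: list[DomainRecord], rmsd_max: float = 7.0,
                        sim_min: float = 10.0, provenance: str = "") -> list[Subgroup]:
    """Greedy leader clustering under the mutual similarity thresholds.

    Domains are processed sorted by descending sequence length, then
    lexicographic id; each joins the first existing subgroup in which it
    satisfies BOTH thresholds against EVERY member, else founds a new one.
    The result is deterministic and every intra-subgroup pair obeys the
    mutual constraints by construction.
    """
    if not domains:
        raise ValueError("no domains to partition")
    by_id = {d.id: d for d in domains}
    ordered = sorted(domains, key=lambda d: (-len(d.sequence), d.id))
    groups: list[Subgroup] = []

    def compatible(d: DomainRecord, other_id: str) -> bool:
        o = by_id[other_id]
        if pair_similarity(d.sequence, o.sequence) <= sim_min:
            return False
        return domain_rmsd(d, o) < rmsd_max

    for d in ordered:
        for g in groups:
            if all(compatible(d, m) for m in g.members):
                g.members.append(d.id)
                break
        else:
            groups.append(Subgroup([d.id], provenance or d.parent_entry))
    return groups
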