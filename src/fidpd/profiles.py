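"""Profile modules: probabilistic consensus of a subgroup MSA plus annotations.

A profile module is a small profile hidden Markov model built from the
multiple sequence alignment of one subgroup, with four annotations used by
the prediction equations:

* ``C`` per column — conservation level in {0, 1, 3, 4} (nonconservative,
  minimally conservative, conservative, highly conservative), a
  deterministic reinterpretation of the four-symbol alignment display
  convention (gap / '+' / lowercase / capital);
* ``S`` per column — the number of member functional sites that map to the
  column through the MSA;
* ``V`` per column — the component-wise sum of the member interaction
  vectors mapping to the column;
* ``N`` per module — the subgroup size (module volume).

Match states are the columns with gap fraction <= 0.5; emissions are
observed frequencies with a Laplace pseudocount (alpha = 1) and transitions
are counted from the observed MSA state paths with a light pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .interactions import InteractionVector

__all__ = ["AA", "Msa", "ProfileColumn", "ProfileModule", "build_profile",
           "conservation_values", "annotate_sites", "annotate_interactions",
           "build_annotated_profile"]

logger = logging.getLogger(__name__)

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_CHARS = {"-", ".", "~"}

#: Laplace pseudocount on emissions (per spec of the column model).
EMISSION_ALPHA = 1.0
#: Pseudocount on transition counts.  Deliberately lighter than the emission
#: prior: with a full count of 1 a single-sequence module pays more for the
#: M->M transition (-1 bit) than a perfectly matching residue earns, and a
#: query identical to the consensus would no longer align end to end.
TRANSITION_ALPHA = 0.1

_TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")


@dataclass
class Msa:
    """A rectangular multiple sequence alignment."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged MSA: rows have different lengths")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    def degapped(self, i: int) -> str:
        return "".join(c for c in self.rows[i] if c not in GAP_CHARS)

    def position_to_column(self, i: int) -> dict[int, int]:
        """Map 1-based sequence positions of row ``i`` to 0-based columns."""
        mapping: dict[int, int] = {}
        pos = 0
        for j, c in enumerate(self.rows[i]):
            if c not in GAP_CHARS:
                pos += 1
                mapping[pos] = j
        return mapping


@dataclass
class ProfileColumn:
    emissions: np.ndarray  # probabilities over the 20 amino acids
    match_state: bool
    C: int = 0
    S: int = 0
    V: InteractionVector = field(default_factory=InteractionVector)


@dataclass
class ProfileModule:
    """An annotated profile HMM over the columns of one subgroup MSA."""

    id: str
    columns: list[ProfileColumn]
    transitions: dict[str, np.ndarray]  # each key in _TRANSITION_KEYS, length M+1
    N: int
    subgroup: str = ""

    @property
    def match_columns(self) -> list[int]:
        return [j for j, c in enumerate(self.columns) if c.match_state]

    @property
    def n_match(self) -> int:
        return sum(1 for c in self.columns if c.match_state)

    def match_emissions(self) -> np.ndarray:
        """(M, 20) emission matrix over match states only."""
        return np.array([c.emissions for c in self.columns if c.match_state])

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "n": self.N,
            "subgroup": self.subgroup,
            "columns": [
                {
                    "e": [round(float(x), 9) for x in c.emissions],
                    "m": c.match_state,
                    "c": c.C,
                    "s": c.S,
                    "v": list(c.V.as_tuple()),
                }
                for c in self.columns
            ],
            "transitions": {k: [round(float(x), 9) for x in v] for k, v in self.transitions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileModule":
        cols = [
            ProfileColumn(np.array(c["e"], float), bool(c["m"]), int(c["c"]),
                          int(c["s"]), InteractionVector.from_tuple(c["v"]))
            for c in d["columns"]
        ]
        tr = {k: np.array(v, float) for k, v in d["transitions"].items()}
        return cls(d["id"], cols, tr, int(d["n"]), d.get("subgroup", ""))


def _state_path(row: str, is_match: list[bool]) -> list[tuple[str, int]]:
    """MSA row -> profile state path [('M'|'D'|'I', match position)]."""
    path: list[tuple[str, int]] = []
    k = 0
    for j, c in enumerate(row):
        if is_match[j]:
            k += 1
            path.append(("M", k) if c not in GAP_CHARS else ("D", k))
        elif c not in GAP_CHARS:
            path.append(("I", k))
    return path


def build_profile(msa: Msa, module_id: str = "", subgroup: str = "") -> ProfileModule:
    """Build the profile HMM of an MSA (no annotations).

    Match states are the columns with gap fraction <= 0.5.  Emissions are
    observed residue frequencies with a Laplace pseudocount; transition
    probabilities are counted from the observed per-row state paths.
    """
    n = msa.n_rows
    is_match = []
    for j in range(msa.n_cols):
        gaps = sum(1 for c in msa.column(j) if c in GAP_CHARS)
        is_match.append(gaps / n <= 0.5)
    background = np.full(len(AA), 1.0 / len(AA))

    columns = []
    for j in range(msa.n_cols):
        if is_match[j]:
            counts = np.full(len(AA), EMISSION_ALPHA)
            for c in msa.column(j):
                if c in AA_INDEX:
                    counts[AA_INDEX[c]] += 1.0
            columns.append(ProfileColumn(counts / counts.sum(), True))
        else:
            columns.append(ProfileColumn(background.copy(), False))

    M = sum(is_match)
    tcounts = {k: np.full(M + 1, TRANSITION_ALPHA) for k in _TRANSITION_KEYS}
    for row in msa.rows:
        path = [("M", 0)] + _state_path(row, is_match) + [("M", M + 1)]
        for (s, k), (s2, k2) in zip(path, path[1:]):
            key = s + s2
            pos = k if k <= M else M
            tcounts[key][pos] += 1.0
    transitions: dict[str, np.ndarray] = {}
    for src in "MID":
        total = sum(tcounts[src + dst] for dst in "MID")
        for dst in "MID":
            transitions[src + dst] = tcounts[src + dst] / total
    return ProfileModule(module_id, columns, transitions, n, subgroup)


def conservation_values(msa: Msa) -> list[int]:
    """Per-column conservation levels C in {0, 1, 3, 4}.

    4: all rows identical and ungapped; 3: modal residue fraction >= 0.8;
    1: fraction of rows in the BLOSUM62-positive class of the modal residue
    >= 0.5; 0 otherwise (including gap-majority columns).
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = msa.n_rows
    out = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        gaps = sum(1 for c in col if c in GAP_CHARS)
        if gaps / n > 0.5:
            out.append(0)
            continue
        residues = [c for c in col if c in AA_INDEX]
        if not residues:
            out.append(0)
            continue
        if gaps == 0 and len(set(col)) == 1:
            out.append(4)
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        modal = min(sorted(counts), key=lambda c: (-counts[c], c))
        if counts[modal] / n >= 0.8:
            out.append(3)
            continue
        positive = sum(1 for c in residues if blosum[modal][c] > 0)
        out.append(1 if positive / n >= 0.5 else 0)
    return out


def _map_member_sites(msa: Msa, member_index: int, member_id: str,
                      positions, values, accumulate) -> None:
    seq_len = len(msa.degapped(member_index))
    posmap = msa.position_to_column(member_index)
    for pos in sorted(positions):
        if pos > seq_len:
            raise ValueError(
                f"member {member_id!r}: site position {pos} beyond sequence length {seq_len}"
            )
        col = posmap[pos]
        accumulate(col, values.get(pos) if values is not None else None)


def annotate_sites(profile: ProfileModule, members, msa: Msa) -> list[int]:
    """Accumulate per-column site counts S from the member annotations.

    ``members`` are the domain records in MSA row order; each member site
    whose sequence position maps to a match column adds 1 to that column's
    S.  Sites landing on insert columns are dropped with a warning.
    """
    S = [0] * msa.n_cols

    for i, member in enumerate(members):
        def bump(col: int, _v, member=member) -> None:
            if profile.columns[col].match_state:
                S[col] += 1
            else:
                logger.warning("member %s: site in insert column %d dropped", member.id, col)

        _map_member_sites(msa, i, member.id, member.site_positions, None, bump)
    for j, c in enumerate(profile.columns):
        c.S = S[j]
    return S


def annotate_interactions(profile: ProfileModule, members, msa: Msa) -> list[InteractionVector]:
    """Accumulate per-column interaction sums V from the member annotations."""
    V = [InteractionVector() for _ in range(msa.n_cols)]

    for i, member in enumerate(members):
        def bump(col: int, vec, member=member) -> None:
            if vec is None:
                return
            if profile.columns[col].match_state:
                V[col] = V[col] + vec
            else:
                logger.warning("member %s: interactions in insert column %d dropped", member.id, col)

        _map_member_sites(msa, i, member.id, sorted(member.site_vectors),
                          member.site_vectors, bump)
    for j, c in enumerate(profile.columns):
        c.V = V[j]
    return V


def build_annotated_profile(msa: Msa, members, module_id: str = "",
                            subgroup: str = "") -> ProfileModule:
    """Build a profile and attach the C, S and V annotations in one call."""
    profile = build_profile(msa, module_id, subgroup)
    for j, cval in enumerate(conservation_values(msa)):
        profile.columns[j].C = cval
    annotate_sites(profile, members, msa)
    annotate_interactions(profile, members, msa)
    return profile
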