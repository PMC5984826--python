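"""Synthetic families, annotated complexes and end-to-end benchmarks.

Every other module of the package is testable without downloads through
this generator:

* :func:`make_family` mutates a random seed sequence into a family of
  homologous members with designated conserved columns (functional-site
  columns are never mutated), aligned trivially column-by-column;
* :func:`make_complex` builds a toy protein-ligand complex on an idealized
  extended backbone (3.8 A C-alpha spacing along x, side chains grown in
  +y, ligands beyond them), planting at chosen site positions geometries
  that satisfy exactly one interaction detector's criterion with margin and
  violate all others — the generated structure is validated against the
  detectors before it is emitted;
* :func:`make_benchmark` combines the two into a miniature database-build
  input plus held-out query mutants and ground truth for end-to-end
  precision/recall/MCC and PLI-recall measurement.

The scaffold makes no claim of physical plausibility (no folding, no
rotamers); it exists to exercise the classifiers and the pipeline.
"""

from __future__ import annotations

import contextlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .families import DomainRecord
from .interactions import COMPONENTS, InteractionVector, interaction_vector
from .profiles import AA, Msa
from .structio import Atom, FunctionalSiteRecord, Ligand, Residue, ResidueRef, Structure, write_structure

__all__ = ["FamilySpec", "FamilyData", "ComplexSpec", "PlantedInteraction",
           "GeometryError", "Benchmark", "QueryRecord", "PLANT_TYPES",
           "make_family", "make_complex", "make_benchmark", "shuffled"]

#: Planted interaction type -> (residue letter, resname, expected vector)
PLANT_TYPES = {
    "hbond_donor": ("S", "SER", (0, 0, 0, 1, 0, 0, 0)),
    "hbond_acceptor": ("S", "SER", (0, 0, 1, 0, 0, 0, 0)),
    "electrostatic": ("D", "ASP", (0, 0, 0, 0, 0, 1, 0)),
    "pistack": ("F", "PHE", (0, 0, 0, 0, 1, 0, 0)),
    "coordinate": ("C", "CYS", (0, 1, 0, 0, 0, 0, 0)),
    "covalent": ("C", "CYS", (1, 0, 0, 0, 0, 0, 0)),
    "vdw": ("A", "ALA", (0, 0, 0, 0, 0, 0, 1)),
}

#: Minimum separation (in residues) between planted positions so that one
#: plant's ligand cannot graze a neighbouring plant's side chain.
MIN_PLANT_SPACING = 3

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


class GeometryError(ValueError):
    """An infeasible or cross-contaminating planted-geometry request."""


@contextlib.contextmanager
def _quiet_ring_warnings():
    """Scaffold residues carry no side chains, so missing-ring warnings from
    the detectors are expected by construction during validation."""
    log = logging.getLogger("fidpd.interactions")
    previous = log.level
    log.setLevel(logging.ERROR)
    try:
        yield
    finally:
        log.setLevel(previous)


@dataclass
class FamilySpec:
    seed_length: int = 60
    n_members: int = 8
    substitution_rate: float = 0.15
    conserved_positions: set[int] = field(default_factory=set)
    site_positions: set[int] = field(default_factory=set)
    rng_seed: int = 0
    indel_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        for p in self.conserved_positions | self.site_positions:
            if not 1 <= p <= self.seed_length:
                raise ValueError(f"position {p} outside 1..{self.seed_length}")
        if not self.site_positions <= self.conserved_positions:
            raise ValueError("site positions must be a subset of conserved positions")


@dataclass
class FamilyData:
    spec: FamilySpec
    ids: list[str]
    sequences: dict[str, str]
    msa: Msa
    site_positions: dict[str, set[int]]  # per member, in member coordinates
    seed_sequence: str


def _mutate(seq: str, spec: FamilySpec, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(seq)):
        if (i + 1) in spec.conserved_positions:
            continue
        if rng.random() < spec.substitution_rate:
            choices = [a for a in AA if a != seq[i]]
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def make_family(spec: FamilySpec, family_id: str = "fam") -> FamilyData:
    """Generate a family of i.i.d. mutants of a random seed sequence.

    Conserved positions are identical across members; the MSA is the
    trivial column-wise alignment unless ``indel_mode`` adds one
    gap-majority insert column.  Reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seed = "".join(AA[i] for i in rng.integers(0, len(AA), size=spec.seed_length))
    ids = [f"{family_id}_m{i + 1}" for i in range(spec.n_members)]
    rows = [_mutate(seed, spec, rng) for _ in ids]
    sites = {mid: set(spec.site_positions) for mid in ids}

    if spec.indel_mode:
        # one insert column after a random non-conserved boundary, occupied
        # by a minority of members so that it cannot become a match state
        col = int(rng.integers(1, spec.seed_length))
        occupants = set(rng.choice(spec.n_members, size=max(1, spec.n_members // 4),
                                   replace=False).tolist())
        new_rows = []
        for i, row in enumerate(rows):
            ins = AA[rng.integers(0, len(AA))] if i in occupants else "-"
            new_rows.append(row[:col] + ins + row[col:])
            if i in occupants:
                sites[ids[i]] = {p + 1 if p > col else p for p in sites[ids[i]]}
        rows = new_rows

    msa = Msa(ids, rows)
    seqs = {mid: msa.degapped(i) for i, mid in enumerate(ids)}
    return FamilyData(spec, ids, seqs, msa, sites, seed)


@dataclass
class PlantedInteraction:
    position: int  # 1-based residue position
    itype: str  # key of PLANT_TYPES

    def __post_init__(self) -> None:
        if self.itype not in PLANT_TYPES:
            raise GeometryError(f"unknown planted interaction type {self.itype!r}")


@dataclass
class ComplexSpec:
    sequence: str
    planted: list[PlantedInteraction] = field(default_factory=list)
    chain_id: str = "A"
    site_name: str = "AC1"

    def __post_init__(self) -> None:
        positions = sorted(p.position for p in self.planted)
        for p in positions:
            if not 1 <= p <= len(self.sequence):
                raise GeometryError(f"planted position {p} outside the sequence")
        for a, b in zip(positions, positions[1:]):
            if b - a < MIN_PLANT_SPACING:
                raise GeometryError(
                    f"planted positions {a} and {b} closer than {MIN_PLANT_SPACING} residues"
                )
        for p in self.planted:
            want = PLANT_TYPES[p.itype][0]
            if self.sequence[p.position - 1] != want:
                raise GeometryError(
                    f"position {p.position}: {p.itype} needs residue {want!r}, "
                    f"sequence has {self.sequence[p.position - 1]!r}"
                )


def _hexagon(center: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = math.radians(-90 + 60 * k)
        pts.append(center + radius * np.array([math.sin(ang), math.cos(ang), 0.0]))
    return pts


def _sidechain_and_ligand(itype: str, ca: np.ndarray):
    """Side-chain atoms and ligand atoms realizing one planted interaction."""
    up = np.array([0.0, 1.0, 0.0])
    side: list[tuple[str, str, np.ndarray]] = []
    lig: list[tuple[str, str, np.ndarray]] = []
    code = "LIG"
    if itype in ("hbond_donor", "hbond_acceptor"):
        cb = ca + 1.53 * up
        og = cb + 1.43 * up
        side = [("CB", "C", cb), ("OG", "O", og)]
        if itype == "hbond_donor":
            # carbonyl acceptor: O 2.9 A above OG, C=O bond 1.23 A (not donor-capable)
            o = og + 2.9 * up
            lig = [("O1", "O", o), ("C1", "C", o + 1.23 * up)]
        else:
            # amine donor: N 2.9 A above OG with one carbon neighbour
            n = og + 2.9 * up
            lig = [("N1", "N", n), ("C1", "C", n + 1.47 * up)]
    elif itype == "electrostatic":
        cb = ca + 1.53 * up
        cg = cb + 1.52 * up
        od1 = cg + 1.25 * up
        od2 = cg + np.array([1.09, -0.62, 0.0])
        side = [("CB", "C", cb), ("CG", "C", cg), ("OD1", "O", od1), ("OD2", "O", od2)]
        n = od1 + 4.2 * up  # inside the 4.5 A electrostatic cutoff
        dirs = [np.array([0.94, 0.33, 0.0]), np.array([-0.47, 0.33, 0.81]),
                np.array([-0.47, 0.33, -0.81])]
        lig = [("N1", "N", n)] + [
            (f"C{i + 1}", "C", n + 1.49 * d) for i, d in enumerate(dirs)
        ]  # tertiary amine: three heavy neighbours, not donor-capable
    elif itype == "pistack":
        cb = ca + 1.53 * up
        center = ca + 4.43 * up
        ring = _hexagon(center)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        side = [("CB", "C", cb)] + [(n, "C", p) for n, p in zip(names, ring)]
        lig_ring = _hexagon(center + np.array([0.0, 0.0, 5.0]))  # centroids 5 A apart
        lig = [(f"C{i + 1}", "C", p) for i, p in enumerate(lig_ring)]
    elif itype == "coordinate":
        cb = ca + 1.53 * up
        sg = cb + 1.81 * up
        side = [("CB", "C", cb), ("SG", "S", sg)]
        lig = [("ZN", "ZN", sg + 2.35 * up)]  # < 2.8 A S-Zn covalent threshold
        code = "ZN"
    elif itype == "covalent":
        cb = ca + 1.53 * up
        sg = cb + 1.81 * up
        side = [("CB", "C", cb), ("SG", "S", sg)]
        lig = [("S1", "S", sg + 2.30 * up)]  # < 2.6 A S-S covalent threshold
        code = "SX"
    elif itype == "vdw":
        cb = ca + 1.53 * up
        side = [("CB", "C", cb)]
        lig = [("C1", "C", cb + 3.65 * up)]  # < 3.9 A C-C vdW threshold
    return side, lig, code


def make_complex(spec: ComplexSpec, structure_id: str = "SYN1"):
    """Build a planted toy complex; returns ``(Structure, pdb_text)``.

    Raises :class:`GeometryError` if the generated geometry fails its own
    planted-interaction validation (each planted site must show exactly the
    expected interaction vector and every other residue an all-zero one).
    """
    serial = 0

    def atom(name, element, coords, ref, kind):
        nonlocal serial
        serial += 1
        return Atom(serial, name, element, tuple(float(c) for c in coords), kind, ref)

    planted_by_pos = {p.position: p for p in spec.planted}
    residues: list[Residue] = []
    ligands: list[Ligand] = []
    for pos, letter in enumerate(spec.sequence, start=1):
        resname = AA3.get(letter.upper(), "UNK")
        plant = planted_by_pos.get(pos)
        if plant is not None:
            resname = PLANT_TYPES[plant.itype][1]
        ref = ResidueRef(spec.chain_id, pos, "", resname)
        ca = np.array([3.8 * (pos - 1), 0.0, 0.0])
        res = Residue(ref)
        res.atoms.append(atom("N", "N", ca + [-1.2, -0.77, 0.0], ref, "polymer"))
        res.atoms.append(atom("CA", "C", ca, ref, "polymer"))
        res.atoms.append(atom("C", "C", ca + [1.2, -0.77, 0.0], ref, "polymer"))
        res.atoms.append(atom("O", "O", ca + [1.2, -2.0, 0.0], ref, "polymer"))
        if plant is not None:
            side, lig, code = _sidechain_and_ligand(plant.itype, ca)
            for name, el, xyz in side:
                res.atoms.append(atom(name, el, xyz, ref, "polymer"))
            lref = ResidueRef(spec.chain_id, 900 + pos, "", code)
            latoms = [atom(name, el, xyz, lref, "het") for name, el, xyz in lig]
            is_metal = len(latoms) == 1 and latoms[0].element in {"ZN", "MG", "MN", "FE",
                                                                  "CA", "NA", "K", "CU",
                                                                  "NI", "CO"}
            ligands.append(Ligand(code, latoms, is_metal, (spec.chain_id, 900 + pos)))
        residues.append(res)

    sites = []
    if planted_by_pos:
        refs = [residues[p - 1].ref for p in sorted(planted_by_pos)]
        sites.append(FunctionalSiteRecord(spec.site_name, refs))
    structure = Structure(structure_id, {spec.chain_id: residues}, ligands, sites)

    with _quiet_ring_warnings():
        _validate_plants(residues, ligands, planted_by_pos)
    return structure, write_structure(structure)


def _validate_plants(residues, ligands, planted_by_pos) -> None:
    for pos, res in enumerate(residues, start=1):
        got = interaction_vector(res, ligands).as_tuple()
        want = PLANT_TYPES[planted_by_pos[pos].itype][2] if pos in planted_by_pos else (0,) * 7
        if got != want:
            raise GeometryError(
                f"residue {pos} ({res.resname}): planted validation failed, "
                f"expected {want}, detectors found {got}"
            )


@dataclass
class QueryRecord:
    id: str
    family_id: str
    sequence: str
    site_positions: set[int]
    site_vectors: dict[int, InteractionVector]
    truth_labels: dict[int, tuple[int, ...]]  # 7 binary flags per site
    pdb_text: str


@dataclass
class Benchmark:
    families: list[FamilyData]
    domains: list[DomainRecord]
    msas: dict[str, Msa]
    queries: list[QueryRecord]
    rng_seed: int
    manifest: dict
    member_pdbs: dict[str, str] = field(default_factory=dict)


DEFAULT_SITE_TYPES = ("hbond_donor", "hbond_acceptor", "electrostatic",
                      "pistack", "coordinate", "vdw")


def _plant_sequence(seq: str, sites: list[int], types) -> str:
    out = list(seq)
    for pos, t in zip(sites, types):
        out[pos - 1] = PLANT_TYPES[t][0]
    return "".join(out)


def _domain_from_complex(member_id: str, family_id: str, seq: str,
                         sites: set[int], structure: Structure) -> DomainRecord:
    chain = structure.chain("A")
    ca = np.full((len(seq), 3), np.nan)
    for i, res in enumerate(chain):
        a = res.atom("CA")
        if a is not None:
            ca[i] = a.coords
    vectors = {
        pos: interaction_vector(chain[pos - 1], structure.ligands) for pos in sorted(sites)
    }
    return DomainRecord(member_id, seq, ca, set(sites), vectors, parent_entry=family_id)


def shuffled(seq: str, rng: np.random.Generator) -> str:
    """A random permutation of a sequence (decoy query)."""
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)


def make_benchmark(n_families: int = 3, n_members: int = 8,
                   substitution_rate: float = 0.15, seed_length: int = 60,
                   site_types=DEFAULT_SITE_TYPES, n_queries_per_family: int = 2,
                   rng_seed: int = 42) -> Benchmark:
    """A miniature end-to-end benchmark: database input, queries and truth.

    Each family carries one planted site per interaction type in
    ``site_types`` (spaced along the chain), identical across members; each
    member and each held-out query mutant gets a planted complex, and the
    truth tables (site positions and structure-derived interaction labels)
    come from the generated structures themselves.
    """
    rng = np.random.default_rng(rng_seed)
    spacing = 2 * MIN_PLANT_SPACING
    first = 8
    sites = [first + spacing * i for i in range(len(site_types))]
    if sites[-1] > seed_length - 4:
        raise GeometryError("seed_length too short for the requested site types")

    families, domains, queries = [], [], []
    msas: dict[str, Msa] = {}
    member_pdbs: dict[str, str] = {}
    for fi in range(n_families):
        fam_id = f"fam{fi + 1}"
        spec = FamilySpec(seed_length, n_members, substitution_rate,
                         set(sites), set(sites), rng_seed=int(rng.integers(0, 2**31 - 1)))
        fam = make_family(spec, fam_id)
        # force the planted residue letters at site columns (conserved, so
        # shared by all members and preserved in query mutants)
        planted_seed = _plant_sequence(fam.seed_sequence, sites, site_types)
        rows = [_plant_sequence(r, sites, site_types) for r in fam.msa.rows]
        fam = FamilyData(spec, fam.ids, dict(zip(fam.ids, rows)), Msa(fam.ids, rows),
                         fam.site_positions, planted_seed)
        families.append(fam)
        msas[fam_id] = fam.msa

        planted = [PlantedInteraction(p, t) for p, t in zip(sites, site_types)]
        for mid in fam.ids:
            seq = fam.sequences[mid]
            structure, pdb_text = make_complex(ComplexSpec(seq, planted), structure_id=mid)
            member_pdbs[mid] = pdb_text
            domains.append(_domain_from_complex(mid, fam_id, seq, set(sites), structure))

        for qi in range(n_queries_per_family):
            qseq = _plant_sequence(_mutate(planted_seed, spec, rng), sites, site_types)
            qid = f"{fam_id}_q{qi + 1}"
            structure, pdb_text = make_complex(ComplexSpec(qseq, planted), structure_id=qid)
            vectors = {
                pos: interaction_vector(structure.chain("A")[pos - 1], structure.ligands)
                for pos in sites
            }
            labels = {pos: tuple(int(v > 0) for v in vec.as_tuple())
                      for pos, vec in vectors.items()}
            queries.append(QueryRecord(qid, fam_id, qseq, set(sites), vectors,
                                       labels, pdb_text))

    manifest = {
        "rng_seed": rng_seed,
        "n_families": n_families,
        "n_members": n_members,
        "substitution_rate": substitution_rate,
        "seed_length": seed_length,
        "site_positions": sites,
        "site_types": list(site_types),
        "component_order": list(COMPONENTS),
    }
    return Benchmark(families, domains, msas, queries, rng_seed, manifest, member_pdbs)
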