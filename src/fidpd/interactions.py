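"""Geometric classification of protein-ligand physicochemical interactions.

Each functional-site residue is characterised against the ligands of its
complex by a 7-dimensional interaction vector

    V = (NCOV, NCOO, NHBA, NHBD, NPI, NELE, NVDW)

counting covalent bonds, coordinate (metal) bonds, H-bond acceptor and
donor contacts, pi-stacking ring pairs, electrostatic contacts and residual
van der Waals contacts.  All criteria operate on heavy atoms; explicit
hydrogens in the input are ignored.

Detection criteria
------------------
covalent / coordinate
    d < R_cov(a) + R_cov(b) + 0.5 A; the pair counts as a coordinate bond
    when the ligand is a metal ion, as a covalent bond otherwise.
hydrogen bond
    donor-acceptor heavy-atom pairs with d(D,A) <= 3.9 A and an
    angle D-A-AA >= 90 deg for at least one acceptor antecedent AA; when an
    idealized hydrogen can be placed from sp2-like local geometry (donor
    with >= 2 bonded heavy neighbours) the classic d(H,A) <= 2.5 A and
    D-H-A >= 90 deg conditions are additionally enforced.
electrostatic
    charged side-chain nitrogen (Arg, His, Lys) within 4.5 A of a ligand
    oxygen that is not part of any cyclized structure, or charged
    side-chain oxygen (Asp, Glu) within 4.5 A of a ligand nitrogen.
pi-stacking
    an aromatic residue ring (Trp, Phe, Tyr, His) and a carbon-dominant
    ligand ring whose centroids lie 4.5-7 A apart, supported by >= 3
    distinct heavy-atom pairs within the same 4.5-7 A window; no further
    orientation test is applied.
van der Waals
    d < vdW(a) + vdW(b) + 0.5 A for pairs not claimed by any interaction
    above (a counted stack claims all of its ring-ring atom pairs).

An atom pair contributes to at most one interaction type; the aggregator
runs the detectors in the precedence order covalent/coordinate -> H-bond ->
electrostatic -> pi-stack -> vdW and threads the claimed pairs through.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .structio import Atom, Ligand, Residue

__all__ = [
    "InteractionVector",
    "RadiiTable",
    "RingSystem",
    "perceive_bonds",
    "find_ligand_rings",
    "find_residue_rings",
    "detect_hbonds",
    "detect_electrostatic",
    "detect_pistack",
    "detect_covalent_coordinate",
    "detect_vdw",
    "interaction_vector",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("NCOV", "NCOO", "NHBA", "NHBD", "NPI", "NELE", "NVDW")

HBOND_DA_MAX = 3.9
HBOND_HA_MAX = 2.5
HBOND_ANGLE_MIN = 90.0
ELE_CUTOFF = 4.5
PI_CENTROID_RANGE = (4.5, 7.0)
PI_PAIR_RANGE = (4.5, 7.0)
PI_MIN_PAIRS = 3
BOND_SLACK = 0.5

AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    ],
}

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
POSITIVE_N = {"ARG": {"NH1", "NH2", "NE"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
NEGATIVE_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


class RadiiTable:
    """Per-element atomic radii with optional (resname, atom name) overrides."""

    def __init__(self, radii: dict[str, float], default: float | None = None,
                 overrides: dict[str, float] | None = None):
        self.radii = {k.upper(): float(v) for k, v in radii.items()}
        self.default = default
        self.overrides = dict(overrides or {})
        for v in self.radii.values():
            if not 0.2 < v < 3.0:
                raise ValueError(f"radius {v} out of the physical range (0.2, 3.0) A")

    @classmethod
    def from_resource(cls, filename: str) -> "RadiiTable":
        text = resources.files("fidpd.data").joinpath(filename).read_text()
        doc = json.loads(text)
        return cls(doc["radii"], doc.get("default"), doc.get("overrides"))

    def radius(self, element: str, resname: str = "", atom_name: str = "") -> float:
        key = f"{resname}:{atom_name}"
        if key in self.overrides:
            return float(self.overrides[key])
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        if self.default is not None:
            logger.warning("no radius for element %r; using fallback %.2f", element, self.default)
            return self.default
        raise KeyError(f"no radius for element {element!r} and no fallback configured")


def covalent_radii() -> RadiiTable:
    return RadiiTable.from_resource("covalent_radii.json")


def vdw_radii() -> RadiiTable:
    return RadiiTable.from_resource("vdw_radii.json")


@dataclass(frozen=True)
class InteractionVector:
    """The 7 non-negative interaction counts of one functional site."""

    ncov: int = 0
    ncoo: int = 0
    nhba: int = 0
    nhbd: int = 0
    npi: int = 0
    nele: int = 0
    nvdw: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.as_tuple()):
            raise ValueError("interaction counts must be non-negative")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.ncov, self.ncoo, self.nhba, self.nhbd, self.npi, self.nele, self.nvdw)

    def __add__(self, other: "InteractionVector") -> "InteractionVector":
        return InteractionVector(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def __bool__(self) -> bool:
        return any(self.as_tuple())

    @classmethod
    def from_tuple(cls, t) -> "InteractionVector":
        return cls(*(int(x) for x in t))


@dataclass
class RingSystem:
    """A cyclic atom system with its centroid and best-fit plane normal."""

    atoms: list[Atom]
    source: str  # "residue-aromatic" | "ligand"
    centroid: np.ndarray
    normal: np.ndarray
    carbon_dominant: bool = True


def _dist(a: Atom, b: Atom) -> float:
    return math.dist(a.coords, b.coords)


def _heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element != "H"]


def _pair(a: Atom, b: Atom) -> tuple[int, int]:
    return (a.serial, b.serial)


def _angle(a, vertex, b) -> float:
    """Angle a-vertex-b in degrees."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def perceive_bonds(atoms: list[Atom], radii: RadiiTable | None = None) -> nx.Graph:
    """Distance-based bond graph: edge iff d(a,b) < R(a) + R(b) + 0.5 A.

    Nodes are atom serials; atoms are attached as node attributes.
    """
    if not atoms:
        raise ValueError("cannot perceive bonds of an empty atom list")
    radii = radii or covalent_radii()
    g = nx.Graph()
    for a in atoms:
        g.add_node(a.serial, atom=a)
    for i, a in enumerate(atoms):
        ra = radii.radius(a.element, a.parent.resname, a.name)
        for b in atoms[i + 1:]:
            rb = radii.radius(b.element, b.parent.resname, b.name)
            if _dist(a, b) < ra + rb + BOND_SLACK:
                g.add_edge(a.serial, b.serial)
    return g


def _make_ring(atoms: list[Atom], source: str) -> RingSystem:
    coords = np.array([a.coords for a in atoms], float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # plane normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    n = np.linalg.norm(normal)
    normal = normal / n if n > 0 else np.array([0.0, 0.0, 1.0])
    carbons = sum(1 for a in atoms if a.element == "C")
    return RingSystem(atoms, source, centroid, normal, carbons > len(atoms) / 2)


def find_ligand_rings(graph: nx.Graph) -> list[RingSystem]:
    """All simple cycles of length 3-8 of a ligand bond graph."""
    rings = []
    for cycle in nx.simple_cycles(graph, length_bound=8):
        if len(cycle) < 3:
            continue
        atoms = [graph.nodes[n]["atom"] for n in cycle]
        rings.append(_make_ring(_heavy(atoms), "ligand"))
    return rings


def find_residue_rings(residue: Residue) -> list[RingSystem]:
    """Canonical aromatic side-chain rings of Trp, Phe, Tyr and His.

    A residue missing any canonical ring atom yields no ring for that cycle
    (logged); non-aromatic residues yield an empty list.
    """
    rings = []
    for names in AROMATIC_RINGS.get(residue.resname, []):
        atoms = [residue.atom(n) for n in names]
        if any(a is None for a in atoms):
            logger.warning("residue %s %s misses ring atoms; ring skipped",
                           residue.resname, residue.ref.key())
            continue
        ring = _make_ring(atoms, "residue-aromatic")
        ring.carbon_dominant = True
        rings.append(ring)
    return rings


def _residue_donors(residue: Residue) -> list[Atom]:
    names = set(_SIDECHAIN_DONORS.get(residue.resname, set()))
    if residue.resname != "PRO":
        names.add("N")
    return [a for a in residue.atoms if a.name in names and a.element != "H"]


def _residue_acceptors(residue: Residue) -> list[Atom]:
    names = set(_SIDECHAIN_ACCEPTORS.get(residue.resname, set())) | {"O", "OXT"}
    return [a for a in residue.atoms if a.name in names and a.element != "H"]


def _ligand_donors(ligand: Ligand, graph: nx.Graph) -> list[Atom]:
    donors = []
    for a in _heavy(ligand.atoms):
        deg = graph.degree(a.serial) if a.serial in graph else 0
        if a.element == "N" and deg < 3:
            donors.append(a)
        elif a.element == "O" and deg == 1:
            # hydroxyl-like oxygen: single neighbour, no short double-bond contact
            nb = next(iter(graph.neighbors(a.serial)))
            if _dist(a, graph.nodes[nb]["atom"]) >= 1.28:
                donors.append(a)
    return donors


def _neighbours(atom: Atom, graph: nx.Graph) -> list[Atom]:
    if atom.serial not in graph:
        return []
    return [graph.nodes[n]["atom"] for n in graph.neighbors(atom.serial)]


def _ideal_hydrogen(donor: Atom, graph: nx.Graph) -> np.ndarray | None:
    """Idealized H position for a donor with >= 2 bonded heavy neighbours."""
    nbs = _neighbours(donor, graph)
    if len(nbs) < 2:
        return None
    d = np.asarray(donor.coords, float)
    direction = np.zeros(3)
    for nb in nbs:
        v = d - np.asarray(nb.coords, float)
        n = np.linalg.norm(v)
        if n > 0:
            direction += v / n
    n = np.linalg.norm(direction)
    if n == 0:
        return None
    return d + direction / n  # 1.0 A N-H / O-H bond


def _hbond_geometry_ok(donor: Atom, acceptor: Atom, acc_neighbours: list[Atom],
                       donor_graph: nx.Graph) -> bool:
    if _dist(donor, acceptor) > HBOND_DA_MAX:
        return False
    if acc_neighbours:
        best = max(_angle(donor.coords, acceptor.coords, aa.coords) for aa in acc_neighbours)
        if best < HBOND_ANGLE_MIN:
            return False
    h = _ideal_hydrogen(donor, donor_graph)
    if h is not None:
        if math.dist(tuple(h), acceptor.coords) > HBOND_HA_MAX:
            return False
        if _angle(donor.coords, h, acceptor.coords) < HBOND_ANGLE_MIN:
            return False
    return True


def detect_hbonds(site_residue: Residue, ligand: Ligand,
                  exclude: set[tuple[int, int]] | None = None,
                  radii: RadiiTable | None = None):
    """Count H-bond acceptor (NHBA) and donor (NHBD) contacts of a residue.

    NHBD counts residue-donor -> ligand-acceptor pairs, NHBA the converse
    role.  Returns ``(nhba, nhbd, pairs)`` where ``pairs`` maps each counted
    (residue atom serial, ligand atom serial) pair once per role.
    """
    exclude = exclude or set()
    radii = radii or covalent_radii()
    res_heavy = _heavy(site_residue.atoms)
    lig_heavy = _heavy(ligand.atoms)
    if not res_heavy or not lig_heavy:
        return 0, 0, set()
    res_graph = perceive_bonds(res_heavy, radii)
    lig_graph = perceive_bonds(lig_heavy, radii)

    donor_pairs: set[tuple[int, int]] = set()
    lig_acceptors = [a for a in lig_heavy if a.element == "O"]
    for d in _residue_donors(site_residue):
        for a in lig_acceptors:
            if _pair(d, a) in exclude or _pair(d, a) in donor_pairs:
                continue
            if _hbond_geometry_ok(d, a, _neighbours(a, lig_graph), res_graph):
                donor_pairs.add(_pair(d, a))
    acceptor_pairs: set[tuple[int, int]] = set()
    res_acceptors = _residue_acceptors(site_residue)
    for d in _ligand_donors(ligand, lig_graph):
        for a in res_acceptors:
            if _pair(a, d) in exclude or _pair(a, d) in acceptor_pairs:
                continue
            if _hbond_geometry_ok(d, a, _neighbours(a, res_graph), lig_graph):
                acceptor_pairs.add(_pair(a, d))
    return len(acceptor_pairs), len(donor_pairs), donor_pairs | acceptor_pairs


def detect_electrostatic(site_residue: Residue, ligand: Ligand,
                         rings: list[RingSystem] | None = None,
                         exclude: set[tuple[int, int]] | None = None,
                         radii: RadiiTable | None = None):
    """Count charged-atom contacts within 4.5 A.

    Positively charged side-chain N (Arg/His/Lys) versus ligand oxygens that
    are not members of any perceived ring, plus negatively charged
    side-chain O (Asp/Glu) versus ligand nitrogens.  Returns
    ``(nele, pairs)``.
    """
    exclude = exclude or set()
    if rings is None:
        lig_heavy = _heavy(ligand.atoms)
        rings = find_ligand_rings(perceive_bonds(lig_heavy, radii or covalent_radii())) if lig_heavy else []
    ring_serials = {a.serial for ring in rings for a in ring.atoms}
    pairs: set[tuple[int, int]] = set()

    pos_names = POSITIVE_N.get(site_residue.resname, set())
    pos_atoms = [a for a in site_residue.atoms if a.name in pos_names]
    for p in pos_atoms:
        for o in _heavy(ligand.atoms):
            if o.element != "O" or o.serial in ring_serials:
                continue
            if _pair(p, o) in exclude:
                continue
            if _dist(p, o) < ELE_CUTOFF:
                pairs.add(_pair(p, o))
    neg_names = NEGATIVE_O.get(site_residue.resname, set())
    neg_atoms = [a for a in site_residue.atoms if a.name in neg_names]
    for q in neg_atoms:
        for n in _heavy(ligand.atoms):
            if n.element != "N":
                continue
            if _pair(q, n) in exclude:
                continue
            if _dist(q, n) < ELE_CUTOFF:
                pairs.add(_pair(q, n))
    return len(pairs), pairs


def detect_pistack(site_residue: Residue, ligand: Ligand,
                   rings: list[RingSystem] | None = None,
                   exclude: set[tuple[int, int]] | None = None,
                   radii: RadiiTable | None = None):
    """Count pi-stacking ring pairs between a residue and a ligand.

    A (residue aromatic ring, carbon-dominant ligand ring) pair is one stack
    when the centroids are 4.5-7 A apart and at least three distinct
    heavy-atom pairs between the rings fall in the same distance window.
    Returns ``(npi, claimed_pairs)`` where a counted stack claims all of its
    ring-ring atom pairs.  Non-aromatic residues yield 0.
    """
    exclude = exclude or set()
    if rings is None:
        lig_heavy = _heavy(ligand.atoms)
        rings = find_ligand_rings(perceive_bonds(lig_heavy, radii or covalent_radii())) if lig_heavy else []
    res_rings = find_residue_rings(site_residue)
    npi = 0
    claimed: set[tuple[int, int]] = set()
    lo, hi = PI_CENTROID_RANGE
    plo, phi = PI_PAIR_RANGE
    for rr in res_rings:
        for lr in rings:
            if not lr.carbon_dominant:
                continue
            cd = float(np.linalg.norm(rr.centroid - lr.centroid))
            if not lo <= cd <= hi:
                continue
            support = [
                _pair(a, b)
                for a in rr.atoms
                for b in lr.atoms
                if _pair(a, b) not in exclude and plo <= _dist(a, b) <= phi
            ]
            if len(set(support)) >= PI_MIN_PAIRS:
                npi += 1
                claimed |= {_pair(a, b) for a in rr.atoms for b in lr.atoms}
    return npi, claimed


def detect_covalent_coordinate(site_residue: Residue, ligand: Ligand,
                               exclude: set[tuple[int, int]] | None = None,
                               radii: RadiiTable | None = None):
    """Count covalent (NCOV) or coordinate (NCOO) bonds to a ligand.

    A heavy-atom pair bonds when d < R_cov(a) + R_cov(b) + 0.5 A; the count
    goes to NCOO when the ligand is a metal ion, to NCOV otherwise.
    Returns ``(ncov, ncoo, pairs)``.
    """
    exclude = exclude or set()
    radii = radii or covalent_radii()
    pairs: set[tuple[int, int]] = set()
    for a in _heavy(site_residue.atoms):
        ra = radii.radius(a.element, a.parent.resname, a.name)
        for b in _heavy(ligand.atoms):
            if _pair(a, b) in exclude:
                continue
            rb = radii.radius(b.element, b.parent.resname, b.name)
            if _dist(a, b) < ra + rb + BOND_SLACK:
                pairs.add(_pair(a, b))
    n = len(pairs)
    return (0, n, pairs) if ligand.is_metal else (n, 0, pairs)


def detect_vdw(site_residue: Residue, ligand: Ligand,
               already_assigned_pairs: set[tuple[int, int]],
               radii: RadiiTable | None = None):
    """Count van der Waals contacts not claimed by any other interaction.

    A heavy-atom pair contacts when d < vdW(a) + vdW(b) + 0.5 A and the pair
    is not in ``already_assigned_pairs``.  Returns ``(nvdw, pairs)``.
    """
    radii = radii or vdw_radii()
    pairs: set[tuple[int, int]] = set()
    for a in _heavy(site_residue.atoms):
        ra = radii.radius(a.element, a.parent.resname, a.name)
        for b in _heavy(ligand.atoms):
            if _pair(a, b) in already_assigned_pairs:
                continue
            rb = radii.radius(b.element, b.parent.resname, b.name)
            if _dist(a, b) < ra + rb + BOND_SLACK:
                pairs.add(_pair(a, b))
    return len(pairs), pairs


def interaction_vector(site_residue: Residue, ligands: list[Ligand],
                       cov_table: RadiiTable | None = None,
                       vdw_table: RadiiTable | None = None) -> InteractionVector:
    """Full 7-component interaction vector of one site residue.

    Runs the detectors in precedence order (covalent/coordinate -> H-bond ->
    electrostatic -> pi-stack -> vdW), summing over all ligands; each atom
    pair contributes to at most one interaction type.
    """
    cov_table = cov_table or covalent_radii()
    vdw_table = vdw_table or vdw_radii()
    total = InteractionVector()
    for ligand in ligands:
        lig_heavy = _heavy(ligand.atoms)
        if not lig_heavy:
            continue
        lig_graph = perceive_bonds(lig_heavy, cov_table)
        rings = find_ligand_rings(lig_graph)
        claimed: set[tuple[int, int]] = set()
        ncov, ncoo, p = detect_covalent_coordinate(site_residue, ligand, claimed, cov_table)
        claimed |= p
        nhba, nhbd, p = detect_hbonds(site_residue, ligand, claimed, cov_table)
        claimed |= p
        nele, p = detect_electrostatic(site_residue, ligand, rings, claimed, cov_table)
        claimed |= p
        npi, p = detect_pistack(site_residue, ligand, rings, claimed, cov_table)
        claimed |= p
        nvdw, _ = detect_vdw(site_residue, ligand, claimed, vdw_table)
        total = total + InteractionVector(ncov, ncoo, nhba, nhbd, npi, nele, nvdw)
    return total
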