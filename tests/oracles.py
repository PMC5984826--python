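"""Independent brute-force oracles for the geometric detectors.

Everything here re-derives interaction counts by direct enumeration over
typed atom pairs with the documented thresholds, sharing no scanning code
with the implementation, so that detector outputs can be cross-checked on
randomized toy complexes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from fidpd.interactions import (
    BOND_SLACK, ELE_CUTOFF, HBOND_ANGLE_MIN, HBOND_DA_MAX, HBOND_HA_MAX,
    NEGATIVE_O, PI_CENTROID_RANGE, PI_MIN_PAIRS, PI_PAIR_RANGE, POSITIVE_N,
    AROMATIC_RINGS, _SIDECHAIN_ACCEPTORS, _SIDECHAIN_DONORS,
    covalent_radii, vdw_radii,
)
from fidpd.structio import Atom, Ligand, Residue, ResidueRef

COV = covalent_radii()
VDW = vdw_radii()

#: canonical heavy-atom names of the residues the toy generator samples
RES_ATOMS = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "CYS": ["CB", "SG"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
}
_ELEMENT = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _el(name: str) -> str:
    return _ELEMENT.get(name[0], "C")


def d(a: Atom, b: Atom) -> float:
    return math.dist(a.coords, b.coords)


def angle(p, vertex, q) -> float:
    u = np.asarray(p) - np.asarray(vertex)
    v = np.asarray(q) - np.asarray(vertex)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def heavy(atoms):
    return [a for a in atoms if a.element != "H"]


def bonded(atoms):
    """Edge list by the covalent distance rule, by direct enumeration."""
    edges = set()
    for a, b in itertools.combinations(heavy(atoms), 2):
        if d(a, b) < COV.radius(a.element) + COV.radius(b.element) + BOND_SLACK:
            edges.add(frozenset((a.serial, b.serial)))
    return edges


def neighbours(atom, atoms):
    edges = bonded(atoms)
    return [b for b in heavy(atoms) if frozenset((atom.serial, b.serial)) in edges]


def cycles_by_enumeration(atoms, bound=8):
    """All distinct simple cycles (3..bound atoms) by exhaustive DFS.

    Each cycle is returned once, as a canonical node tuple anchored at its
    smallest serial with the lexicographically smaller direction.
    """
    hs = heavy(atoms)
    edges = bonded(hs)
    adj: dict[int, set[int]] = {a.serial: set() for a in hs}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    cycles: set[tuple[int, ...]] = set()

    def dfs(start, path, visited):
        cur = path[-1]
        for nb in adj[cur]:
            if nb == start and len(path) >= 3:
                rest = tuple(path[1:])
                cycles.add((start,) + min(rest, tuple(reversed(rest))))
            elif nb not in visited and nb > start and len(path) < bound:
                dfs(start, path + [nb], visited | {nb})

    for s in sorted(adj):
        dfs(s, [s], {s})
    return cycles


def oracle_cov_coo(res: Residue, lig: Ligand):
    n = 0
    for a in heavy(res.atoms):
        for b in heavy(lig.atoms):
            if d(a, b) < COV.radius(a.element) + COV.radius(b.element) + BOND_SLACK:
                n += 1
    return (0, n) if lig.is_metal else (n, 0)


def _ideal_h(donor, res_atoms):
    nbs = neighbours(donor, res_atoms)
    if len(nbs) < 2:
        return None
    vec = np.zeros(3)
    for nb in nbs:
        v = np.asarray(donor.coords) - np.asarray(nb.coords)
        vec += v / np.linalg.norm(v)
    if np.linalg.norm(vec) == 0:
        return None
    return np.asarray(donor.coords) + vec / np.linalg.norm(vec)


def _hb_ok(donor, donor_unit, acceptor, acceptor_unit):
    if d(donor, acceptor) > HBOND_DA_MAX:
        return False
    aas = neighbours(acceptor, acceptor_unit)
    if aas and max(angle(donor.coords, acceptor.coords, aa.coords) for aa in aas) < HBOND_ANGLE_MIN:
        return False
    h = _ideal_h(donor, donor_unit)
    if h is not None:
        if math.dist(tuple(h), acceptor.coords) > HBOND_HA_MAX:
            return False
        if angle(donor.coords, h, acceptor.coords) < HBOND_ANGLE_MIN:
            return False
    return True


def oracle_hbonds(res: Residue, lig: Ligand):
    donors = set(_SIDECHAIN_DONORS.get(res.resname, set()))
    if res.resname != "PRO":
        donors.add("N")
    acceptors = set(_SIDECHAIN_ACCEPTORS.get(res.resname, set())) | {"O", "OXT"}
    lig_heavy = heavy(lig.atoms)
    nhbd = sum(
        1
        for da in heavy(res.atoms) if da.name in donors
        for aa in lig_heavy if aa.element == "O"
        if _hb_ok(da, heavy(res.atoms), aa, lig.atoms)
    )
    lig_donors = []
    for a in lig_heavy:
        nbs = neighbours(a, lig.atoms)
        if a.element == "N" and len(nbs) < 3:
            lig_donors.append(a)
        elif a.element == "O" and len(nbs) == 1 and d(a, nbs[0]) >= 1.28:
            lig_donors.append(a)
    nhba = sum(
        1
        for da in lig_donors
        for aa in heavy(res.atoms) if aa.name in acceptors
        if _hb_ok(da, lig.atoms, aa, heavy(res.atoms))
    )
    return nhba, nhbd


def oracle_ele(res: Residue, lig: Ligand):
    ring_serials = set().union(*cycles_by_enumeration(lig.atoms)) if heavy(lig.atoms) else set()
    n = 0
    for a in res.atoms:
        if a.name in POSITIVE_N.get(res.resname, set()):
            for o in heavy(lig.atoms):
                if o.element == "O" and o.serial not in ring_serials and d(a, o) < ELE_CUTOFF:
                    n += 1
        if a.name in NEGATIVE_O.get(res.resname, set()):
            for b in heavy(lig.atoms):
                if b.element == "N" and d(a, b) < ELE_CUTOFF:
                    n += 1
    return n


def oracle_pistack(res: Residue, lig: Ligand):
    res_rings = []
    for names in AROMATIC_RINGS.get(res.resname, []):
        atoms = [res.atom(n) for n in names]
        if all(a is not None for a in atoms):
            res_rings.append(atoms)
    lig_cycles = cycles_by_enumeration(lig.atoms)
    by_serial = {a.serial: a for a in lig.atoms}
    n = 0
    for rr in res_rings:
        rc = np.mean([a.coords for a in rr], axis=0)
        for cyc in lig_cycles:
            atoms = [by_serial[s] for s in cyc]
            if sum(1 for a in atoms if a.element == "C") * 2 <= len(atoms):
                continue
            lc = np.mean([a.coords for a in atoms], axis=0)
            cd = float(np.linalg.norm(rc - lc))
            if not PI_CENTROID_RANGE[0] <= cd <= PI_CENTROID_RANGE[1]:
                continue
            support = sum(
                1 for a in rr for b in atoms
                if PI_PAIR_RANGE[0] <= d(a, b) <= PI_PAIR_RANGE[1]
            )
            if support >= PI_MIN_PAIRS:
                n += 1
    return n


def oracle_vdw(res: Residue, lig: Ligand, excluded):
    n = 0
    for a in heavy(res.atoms):
        for b in heavy(lig.atoms):
            if (a.serial, b.serial) in excluded:
                continue
            if d(a, b) < VDW.radius(a.element) + VDW.radius(b.element) + BOND_SLACK:
                n += 1
    return n


_serial_counter = itertools.count(1)


def make_atom(name, element, coords, ref, kind="polymer"):
    return Atom(next(_serial_counter), name, element,
                tuple(float(c) for c in coords), kind, ref)


def random_toy(rng: np.random.Generator):
    """A random residue plus a random nearby ligand (occasionally cyclic)."""
    resname = list(RES_ATOMS)[rng.integers(0, len(RES_ATOMS))]
    ref = ResidueRef("A", 1, "", resname)
    res = Residue(ref)
    for name in ["N", "CA", "C", "O"] + RES_ATOMS[resname]:
        res.atoms.append(make_atom(name, _el(name), rng.uniform(0, 6, 3), ref))

    lref = ResidueRef("A", 900, "", "LIG")
    atoms = []
    if rng.random() < 0.15:
        atoms.append(make_atom("ZN", "ZN", rng.uniform(1, 7, 3), lref, "het"))
        lig = Ligand("ZN", atoms, True, ("A", 900))
        return res, lig
    n_atoms = int(rng.integers(2, 7))
    elements = ["C", "N", "O", "S"]
    for i in range(n_atoms):
        el = elements[rng.integers(0, len(elements))]
        atoms.append(make_atom(f"{el}{i + 1}", el, rng.uniform(1, 7, 3), lref, "het"))
    if rng.random() < 0.5:
        center = rng.uniform(2, 6, 3)
        for k in range(6):
            ang = math.radians(60 * k)
            xyz = center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
            atoms.append(make_atom(f"CR{k + 1}", "C", xyz, lref, "het"))
    return res, Ligand("LIG", atoms, False, ("A", 900))
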