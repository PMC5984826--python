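import math

import numpy as np
import pytest

import oracles
from fidpd.interactions import (InteractionVector, detect_covalent_coordinate,
                                detect_electrostatic, detect_hbonds,
                                detect_pistack, detect_vdw, find_ligand_rings,
                                find_residue_rings, interaction_vector,
                                perceive_bonds)
from fidpd.structio import Ligand, Residue, ResidueRef
from oracles import make_atom


def _residue(resname, atoms):
    ref = ResidueRef("A", 1, "", resname)
    res = Residue(ref)
    for name, el, xyz in atoms:
        res.atoms.append(make_atom(name, el, xyz, ref))
    return res


def _ligand(atoms, code="LIG", metal=False):
    ref = ResidueRef("A", 900, "", code)
    return Ligand(code, [make_atom(n, e, x, ref, "het") for n, e, x in atoms],
                  metal, ("A", 900))


class TestBondsAndRings:
    def test_carbon_pair_bonding_threshold(self):
        # R_C = 0.77: bonded below 2.04 A, not above
        near = [make_atom("C1", "C", (0, 0, 0), ResidueRef("A", 1, "", "LIG")),
                make_atom("C2", "C", (1.5, 0, 0), ResidueRef("A", 1, "", "LIG"))]
        assert perceive_bonds(near).number_of_edges() == 1
        far = [make_atom("C1", "C", (0, 0, 0), ResidueRef("A", 1, "", "LIG")),
               make_atom("C2", "C", (2.2, 0, 0), ResidueRef("A", 1, "", "LIG"))]
        assert perceive_bonds(far).number_of_edges() == 0

    def test_benzene_ring_is_one_six_cycle(self):
        ref = ResidueRef("A", 900, "", "BNZ")
        atoms = [make_atom(f"C{k}", "C",
                           (1.39 * math.cos(math.radians(60 * k)),
                            1.39 * math.sin(math.radians(60 * k)), 0.0), ref, "het")
                 for k in range(6)]
        g = perceive_bonds(atoms)
        assert g.number_of_edges() == 6
        rings = find_ligand_rings(g)
        assert len(rings) == 1 and len(rings[0].atoms) == 6
        assert np.linalg.norm(rings[0].centroid) == pytest.approx(0.0, abs=1e-9)
        assert abs(rings[0].normal[2]) == pytest.approx(1.0)

    def test_ligand_cycles_match_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            _, lig = oracles.random_toy(rng)
            if lig.is_metal:
                continue
            got = find_ligand_rings(perceive_bonds([a for a in lig.atoms]))
            want = oracles.cycles_by_enumeration(lig.atoms)
            assert len(got) == len(want)

    def test_residue_rings(self):
        phe = _residue("PHE", [(n, "C", (k, 0, 0)) for k, n in
                               enumerate(["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])])
        assert len(find_residue_rings(phe)) == 1
        ala = _residue("ALA", [("CB", "C", (0, 0, 0))])
        assert find_residue_rings(ala) == []
        trp_incomplete = _residue("TRP", [("CG", "C", (0, 0, 0))])
        assert find_residue_rings(trp_incomplete) == []


class TestDetectorExamples:
    def test_ser_donor_to_carbonyl_oxygen(self):
        res = _residue("SER", [("CB", "C", (0, 0, 0)), ("OG", "O", (0, 1.43, 0))])
        lig = _ligand([("O1", "O", (0, 4.33, 0)), ("C1", "C", (0, 5.56, 0))])
        nhba, nhbd, _ = detect_hbonds(res, lig)
        assert nhbd >= 1 and nhba == 0

    def test_distant_pairs_no_hbond(self):
        res = _residue("SER", [("OG", "O", (0, 0, 0))])
        lig = _ligand([("O1", "O", (0, 4.0, 0))])
        assert detect_hbonds(res, lig)[:2] == (0, 0)

    def test_bad_acceptor_antecedent_angle_rejected(self):
        # D-A 3.0 A but the acceptor's neighbour sits between: D-A-AA = 45 deg
        res = _residue("SER", [("OG", "O", (0, 0, 0))])
        aa = (3.0 - 1.23 * math.cos(math.radians(45)), 1.23 * math.sin(math.radians(45)), 0)
        lig = _ligand([("O1", "O", (3.0, 0, 0)), ("C1", "C", aa)])
        assert detect_hbonds(res, lig)[:2] == (0, 0)

    def test_lysine_electrostatic_with_ring_exclusion(self):
        res = _residue("LYS", [("NZ", "N", (0, 0, 0))])
        free_o = _ligand([("O1", "O", (3.5, 0, 0)), ("P1", "P", (5.0, 0, 0))])
        assert detect_electrostatic(res, free_o)[0] == 1
        # furanose-like ring oxygen 3.5 A away is excluded
        ring = [("O1", "O", (3.5, 0, 0))]
        for k in range(4):
            ang = math.radians(72 * (k + 1))
            ring.append((f"C{k + 1}", "C",
                         (3.5 + 1.4 * (1 - math.cos(ang)) * 0.8, 1.4 * math.sin(ang), 0)))
        # build an explicit closed 5-ring instead: regular pentagon of side ~1.45
        center = np.array([4.7, 0, 0])
        ring = []
        for k, el in enumerate(["O", "C", "C", "C", "C"]):
            ang = math.radians(180 + 72 * k)
            xyz = center + 1.23 * np.array([math.cos(ang), math.sin(ang), 0])
            ring.append((f"{el}{k + 1}", el, tuple(xyz)))
        ringed = _ligand(ring)
        assert len(find_ligand_rings(perceive_bonds(ringed.atoms))) >= 1
        assert detect_electrostatic(res, ringed)[0] == 0

    def test_asp_beyond_cutoff(self):
        res = _residue("ASP", [("OD1", "O", (0, 0, 0))])
        lig = _ligand([("N1", "N", (5.0, 0, 0))])
        assert detect_electrostatic(res, lig)[0] == 0

    def _stacked_pair(self, resname, centroid_dz):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        res_atoms = []
        for k, n in enumerate(names):
            ang = math.radians(60 * k)
            res_atoms.append((n, "C", (1.39 * math.cos(ang), 1.39 * math.sin(ang), 0)))
        res = _residue(resname, res_atoms + [("OH", "O", (2.8, 0, 0))] * (resname == "TYR"))
        lig_atoms = []
        for k in range(6):
            ang = math.radians(60 * k)
            lig_atoms.append((f"C{k + 1}", "C",
                              (1.39 * math.cos(ang), 1.39 * math.sin(ang), centroid_dz)))
        return res, _ligand(lig_atoms)

    def test_parallel_rings_at_5A_stack(self):
        res, lig = self._stacked_pair("TYR", 5.0)
        assert detect_pistack(res, lig)[0] == 1

    def test_rings_at_8A_do_not_stack(self):
        res, lig = self._stacked_pair("TYR", 8.0)
        assert detect_pistack(res, lig)[0] == 0

    def test_nonaromatic_residue_never_stacks(self):
        res, lig = self._stacked_pair("LEU", 5.0)
        assert detect_pistack(res, lig)[0] == 0

    def test_cys_covalent_to_ligand_carbon(self):
        res = _residue("CYS", [("SG", "S", (0, 0, 0))])
        lig = _ligand([("C1", "C", (1.9, 0, 0))])
        assert detect_covalent_coordinate(res, lig)[:2] == (1, 0)

    def test_his_coordinate_to_zinc(self):
        res = _residue("HIS", [("NE2", "N", (0, 0, 0))])
        lig = _ligand([("ZN", "ZN", (2.1, 0, 0))], code="ZN", metal=True)
        assert detect_covalent_coordinate(res, lig)[:2] == (0, 1)

    def test_separated_atoms_no_bond(self):
        res = _residue("CYS", [("SG", "S", (0, 0, 0))])
        lig = _ligand([("C1", "C", (3.5, 0, 0))])
        assert detect_covalent_coordinate(res, lig)[:2] == (0, 0)

    def test_vdw_threshold_and_exclusion(self):
        res = _residue("ALA", [("CB", "C", (0, 0, 0))])
        lig = _ligand([("C1", "C", (3.8, 0, 0))])
        assert detect_vdw(res, lig, set())[0] == 1  # 3.8 < 1.7 + 1.7 + 0.5
        lig_far = _ligand([("C1", "C", (4.0, 0, 0))])
        assert detect_vdw(res, lig_far, set())[0] == 0
        claimed = {(res.atoms[0].serial, lig.atoms[0].serial)}
        assert detect_vdw(res, lig, claimed)[0] == 0


class TestOracleEquivalence:
    N_INSTANCES = 500

    def test_detectors_agree_with_bruteforce_on_random_toys(self):
        rng = np.random.default_rng(20240817)
        for _ in range(self.N_INSTANCES):
            res, lig = oracles.random_toy(rng)
            ncov, ncoo, _ = detect_covalent_coordinate(res, lig)
            assert (ncov, ncoo) == oracles.oracle_cov_coo(res, lig)
            nhba, nhbd, _ = detect_hbonds(res, lig)
            assert (nhba, nhbd) == oracles.oracle_hbonds(res, lig)
            assert detect_electrostatic(res, lig)[0] == oracles.oracle_ele(res, lig)
            assert detect_pistack(res, lig)[0] == oracles.oracle_pistack(res, lig)
            assert detect_vdw(res, lig, set())[0] == oracles.oracle_vdw(res, lig, set())

    def test_vector_disjointness_against_chained_oracle(self):
        """Atom pairs contribute to at most one component of the vector."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            res, lig = oracles.random_toy(rng)
            v = interaction_vector(res, [lig])
            claimed = set()
            ncov, ncoo, p = detect_covalent_coordinate(res, lig, claimed)
            claimed |= p
            nhba, nhbd, p = detect_hbonds(res, lig, claimed)
            claimed |= p
            nele, p = detect_electrostatic(res, lig, None, claimed)
            claimed |= p
            npi, p = detect_pistack(res, lig, None, claimed)
            claimed |= p
            nvdw, _ = detect_vdw(res, lig, claimed)
            assert v.as_tuple() == (ncov, ncoo, nhba, nhbd, npi, nele, nvdw)


class TestVectorProperties:
    def test_far_ligand_all_zero(self):
        res = _residue("SER", [("OG", "O", (0, 0, 0))])
        lig = _ligand([("O1", "O", (10, 0, 0))])
        assert interaction_vector(res, [lig]).as_tuple() == (0,) * 7

    def test_additive_over_ligands(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            res, lig1 = oracles.random_toy(rng)
            _, lig2 = oracles.random_toy(rng)
            combined = interaction_vector(res, [lig1, lig2])
            parts = interaction_vector(res, [lig1]) + interaction_vector(res, [lig2])
            assert combined.as_tuple() == parts.as_tuple()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        from scipy.spatial.transform import Rotation
        for _ in range(30):
            res, lig = oracles.random_toy(rng)
            base = interaction_vector(res, [lig]).as_tuple()
            R = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
            t = rng.uniform(-20, 20, 3)
            for atom in res.atoms + lig.atoms:
                atom.coords = tuple(R @ np.asarray(atom.coords) + t)
            assert interaction_vector(res, [lig]).as_tuple() == base

    def test_translating_planted_ligand_away_is_monotone(self):
        from fidpd.fixtures import ComplexSpec, PLANT_TYPES, PlantedInteraction, make_complex
        for itype in PLANT_TYPES:
            seq = list("G" * 15)
            seq[7] = PLANT_TYPES[itype][0]
            structure, _ = make_complex(ComplexSpec("".join(seq), [PlantedInteraction(8, itype)]))
            res = structure.chain("A")[7]
            lig = structure.ligands[0]
            prev = sum(interaction_vector(res, [lig]).as_tuple())
            for dy in (1.0, 2.0, 4.0, 8.0):
                moved = Ligand(lig.het_code, [
                    make_atom(a.name, a.element,
                              (a.coords[0], a.coords[1] + dy, a.coords[2]),
                              a.parent, "het") for a in lig.atoms
                ], lig.is_metal, lig.instance_id)
                cur = sum(interaction_vector(res, [moved]).as_tuple())
                assert cur <= prev
                prev = cur

    def test_vector_arithmetic(self):
        a = InteractionVector(0, 0, 1, 0, 0, 0, 2)
        b = InteractionVector(0, 0, 0, 1, 0, 0, 1)
        assert (a + b).as_tuple() == (0, 0, 1, 1, 0, 0, 3)
        with pytest.raises(ValueError):
            InteractionVector(-1)
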