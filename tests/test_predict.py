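import numpy as np
import pytest

from fidpd.interactions import InteractionVector
from fidpd.predict import (chemical_postfilter, fscore, iscore,
                           normalize_scores, predict, select_by_scale,
                           select_n_top)
from fidpd.profiles import Msa, build_profile
from fidpd.search import ProfileHit


def _module(module_id="p1", n=10, S=(), C=(), V=None):
    p = build_profile(Msa(["s1"], ["ACDEFGHIKL"]), module_id)
    p.N = n
    for col, s in S:
        p.columns[col].S = s
    for col, c in C:
        p.columns[col].C = c
    for col, v in (V or []):
        p.columns[col].V = v
    return p


class TestScoring:
    def test_no_hits_all_zero(self):
        assert fscore(5, [], {}).tolist() == [0.0] * 5

    def test_single_hit_product(self):
        # S=2, C=4, N=10, E=19 -> F = 2*4*10*19 = 1520
        p = _module(S=[(2, 2)], C=[(2, 4)])
        hit = ProfileHit("p1", 50.0, 1e-19, 19.0, [(7, 2)])
        F = fscore(12, [hit], {"p1": p})
        assert F[6] == pytest.approx(1520.0)
        assert F.sum() == pytest.approx(1520.0)

    def test_hits_add(self):
        p1 = _module("p1", n=10, S=[(0, 2)], C=[(0, 4)])
        p2 = _module("p2", n=5, S=[(0, 1)], C=[(0, 3)])
        h1 = ProfileHit("p1", 50.0, 1e-19, 19.0, [(3, 0)])
        h2 = ProfileHit("p2", 30.0, 1e-20, 20.0, [(3, 0)])
        F = fscore(5, [h1, h2], {"p1": p1, "p2": p2})
        assert F[2] == pytest.approx(2 * 4 * 10 * 19 + 1 * 3 * 5 * 20)

    def test_bad_column_reference_is_error(self):
        p = _module()
        with pytest.raises(ValueError, match="column"):
            fscore(5, [ProfileHit("p1", 1, 1e-9, 9, [(1, 99)])], {"p1": p})

    def test_iscore_scalar_multiplication(self):
        v = InteractionVector(0, 0, 1, 0, 0, 0, 2)
        p = _module(S=[(1, 1)], C=[(1, 4)], V=[(1, v)])
        hit = ProfileHit("p1", 50.0, 1e-19, 19.0, [(4, 1)])
        I = iscore(6, [hit], {"p1": p})
        assert I[3].tolist() == [0, 0, 760, 0, 0, 0, 1520]
        assert I.sum() == pytest.approx(760 + 1520)

    def test_escore_scaling_leaves_selection_unchanged(self):
        rng = np.random.default_rng(0)
        p = _module(S=[(i, int(s)) for i, s in enumerate(rng.integers(0, 3, 10))],
                    C=[(i, 4) for i in range(10)])
        hit = ProfileHit("p1", 50.0, 1e-19, 19.0, [(i + 1, i) for i in range(10)])
        F1 = fscore(10, [hit], {"p1": p})
        hit2 = ProfileHit("p1", 50.0, 1e-19, 19.0 * 7.5, hit.map)
        F2 = fscore(10, [hit2], {"p1": p})
        assert select_by_scale(F1) == select_by_scale(F2)


class TestSelection:
    def test_scale_rule_worked_example(self):
        F = np.array([100.0, 50.0, 40.0, 30.0, 10.0])
        # M=35 keeps {100, 50, 40}; ceil(0.45 * 3) = 2 -> top two
        assert select_by_scale(F, 35, 45) == [1, 2]

    def test_all_zero_empty(self):
        assert select_by_scale(np.zeros(4)) == []

    def test_subthreshold_positions_irrelevant(self):
        F = np.array([100.0, 50.0, 40.0, 30.0, 10.0])
        F2 = np.concatenate([F, [1.0, 2.0, 3.0]])
        assert select_by_scale(F, 35, 45) == select_by_scale(F2, 35, 45)

    def test_n_top_with_ties(self):
        assert select_n_top(np.array([5.0, 9.0, 9.0, 1.0]), 2) == [2, 3]

    def test_n_top_limited_by_nonzero(self):
        assert select_n_top(np.array([0.0, 3.0, 0.0, 1.0]), 10) == [2, 4]


class TestNormalization:
    def test_endpoints(self):
        F = np.array([760.0, 380.0])
        assert normalize_scores(F, [1, 2]) == {1: 100.0, 2: 1.0}

    def test_single_site_is_100(self):
        assert normalize_scores(np.array([42.0]), [1]) == {1: 100.0}

    def test_order_preserved(self):
        F = np.array([5.0, 50.0, 20.0, 35.0])
        norm = normalize_scores(F, [1, 2, 3, 4])
        order = sorted(norm, key=norm.get)
        assert order == sorted(range(1, 5), key=lambda p: F[p - 1])


class TestPostfilter:
    LABELS = {1: (0, 0, 0, 0, 1, 1, 0)}

    def test_leucine_pi_suppressed(self):
        out = chemical_postfilter("L", [1], self.LABELS)
        assert out[1][4] == 0

    def test_histidine_keeps_both(self):
        out = chemical_postfilter("H", [1], self.LABELS)
        assert out[1][4] == 1 and out[1][5] == 1

    def test_threonine_electrostatic_suppressed(self):
        out = chemical_postfilter("T", [1], self.LABELS)
        assert out[1][5] == 0

    def test_never_adds_labels_and_idempotent(self):
        labels = {1: (1, 1, 1, 1, 1, 1, 1)}
        once = chemical_postfilter("G", [1], labels)
        twice = chemical_postfilter("G", [1], once)
        assert once == twice
        assert all(a <= b for a, b in zip(once[1], labels[1]))


class TestEndToEnd:
    def test_planted_sites_recovered_with_labels(self, benchmark, fitted):
        q = benchmark.queries[0]
        result = predict(q.sequence, fitted.database_, n_top=len(q.site_positions))
        assert result.selected_positions() == q.site_positions
        for site in result.sites:
            assert site.labels == q.truth_labels[site.position]
            assert 1.0 <= site.normalized <= 100.0

    def test_scale_selection_obeys_ceil_rule(self, benchmark, fitted):
        import math
        q = benchmark.queries[0]
        result = predict(q.sequence, fitted.database_, M_pct=35, T_pct=45)
        F = fscore(len(q.sequence), result.hits,
                   {m.id: m for m in fitted.database_.modules})
        retained = sum(F >= 0.35 * F.max())
        assert len(result.sites) == math.ceil(0.45 * retained)

    def test_shuffled_query_no_hit(self, benchmark, fitted):
        rng = np.random.default_rng(23)
        seq = list(benchmark.queries[0].sequence)
        rng.shuffle(seq)
        result = predict("".join(seq), fitted.database_)
        assert result.no_hit and result.sites == []
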