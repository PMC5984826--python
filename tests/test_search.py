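import math

import numpy as np
import pytest

from fidpd.profiles import AA, AA_INDEX, Msa, build_profile
from fidpd.search import (NO_HIT, GumbelParams, NoHit, ProfileDatabase,
                          calibrate, evalue, scan, viterbi_align)


def brute_force_best(profile, seq):
    """Exhaustive enumeration of all local state paths (small cases only).

    A path enters at any match state, may use interior insert/delete
    states, and exits at any match state; transition scores are log2
    probabilities, match emissions log-odds bits, insert emissions 0.
    """
    em = np.log2(np.maximum(profile.match_emissions(), 1e-300) * len(AA))
    tr = {k: np.log2(np.maximum(v, 1e-300)) for k, v in profile.transitions.items()}
    Mn, L = profile.n_match, len(seq)
    x = [AA_INDEX.get(c, -1) for c in seq]

    def e(k, i):
        return em[k - 1][x[i - 1]] if x[i - 1] >= 0 else 0.0

    best = -math.inf

    def extend(state, k, i, score):
        nonlocal best
        if state == "M":
            best = max(best, score)  # may exit here
        if k < Mn and i < L:
            for nxt in "MID":
                pass
        # transitions out
        if k < Mn:
            if i < L:
                extend("M", k + 1, i + 1, score + tr[state + "M"][k] + e(k + 1, i + 1))
            extend("D", k + 1, i, score + tr[state + "D"][k])
        if i < L:
            extend("I", k, i + 1, score + tr[state + "I"][k])

    for k0 in range(1, Mn + 1):
        for i0 in range(1, L + 1):
            extend("M", k0, i0, e(k0, i0))
    return best


def random_profile(rng, n_cols, n_rows=3):
    rows = ["".join(AA[i] for i in rng.integers(0, 20, n_cols)) for _ in range(n_rows)]
    return build_profile(Msa([f"s{i}" for i in range(n_rows)], rows))


class TestViterbi:
    def test_consensus_query_maps_identity(self):
        p = build_profile(Msa(["s1"], ["ACDEFGHIKL"]))
        score, pairs = viterbi_align(p, "ACDEFGHIKL")
        assert score > 0
        assert pairs == [(i + 1, i) for i in range(10)]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = random_profile(rng, int(rng.integers(1, 6)))
            seq = "".join(AA[i] for i in rng.integers(0, 20, int(rng.integers(1, 8))))
            got, _ = viterbi_align(p, seq)
            want = brute_force_best(p, seq)
            assert got == pytest.approx(max(want, 0.0), abs=1e-9)

    def test_appending_noise_never_lowers_local_score(self):
        rng = np.random.default_rng(5)
        p = random_profile(rng, 8)
        seq = "ACDEFGHIKL"
        base, _ = viterbi_align(p, seq)
        longer, _ = viterbi_align(p, seq + "WWWWYYYY")
        assert longer >= base - 1e-12

    def test_map_strictly_increasing(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = random_profile(rng, 12)
            seq = "".join(AA[i] for i in rng.integers(0, 20, 25))
            _, pairs = viterbi_align(p, seq)
            qs = [q for q, _ in pairs]
            cs = [c for _, c in pairs]
            assert qs == sorted(qs) and len(set(qs)) == len(qs)
            assert cs == sorted(cs) and len(set(cs)) == len(cs)

    def test_empty_sequence_is_error(self):
        p = random_profile(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            viterbi_align(p, "")


class TestCalibration:
    def test_same_seed_identical(self):
        p = random_profile(np.random.default_rng(1), 10)
        a = calibrate(p, n_decoys=60, seed=7, length=30)
        b = calibrate(p, n_decoys=60, seed=7, length=30)
        assert a == b

    def test_tail_probability_near_nominal(self):
        p = random_profile(np.random.default_rng(2), 10)
        params = calibrate(p, n_decoys=400, seed=3, length=30)
        rng = np.random.default_rng(99)
        scores = []
        for _ in range(400):
            seq = "".join(AA[i] for i in rng.integers(0, 20, 30))
            scores.append(viterbi_align(p, seq)[0])
        s95 = np.quantile(scores, 0.95)
        # fitted survival at the empirical 95th percentile ~ 0.05
        surv = 1 - math.exp(-math.exp(-params.lam * (s95 - params.mu)))
        assert 0.02 < surv < 0.10

    def test_more_decoys_shrink_parameter_spread(self):
        p = random_profile(np.random.default_rng(4), 8)
        small = [calibrate(p, 50, seed=s, length=25).mu for s in range(8)]
        large = [calibrate(p, 400, seed=s, length=25).mu for s in range(8)]
        assert np.std(large) < np.std(small)

    def test_too_few_decoys_rejected(self):
        p = random_profile(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            calibrate(p, n_decoys=10, seed=0, length=10)


class TestEvalue:
    def test_closed_forms(self):
        params = GumbelParams(mu=10.0, lam=0.7)
        assert evalue(10.0, params, 1) == pytest.approx(1.0)
        assert evalue(10.0 + math.log(10) / 0.7, params, 1) == pytest.approx(0.1)
        assert evalue(5.0, params, 3) == pytest.approx(3 * math.exp(-0.7 * -5.0))

    def test_monotone_decreasing_and_clamped(self):
        params = GumbelParams(mu=5.0, lam=1.0)
        scores = [0.0, 5.0, 20.0, 2000.0]
        evs = [evalue(s, params, 4) for s in scores]
        assert evs == sorted(evs, reverse=True)
        assert evs[-1] >= 1e-300


class TestScan:
    def test_family_member_query_hits_own_module(self, benchmark, fitted):
        db = fitted.database_
        member = benchmark.domains[0]
        hits = scan(member.sequence, db)
        assert not isinstance(hits, NoHit)
        assert hits[0].profile_id.startswith(member.parent_entry)
        assert all(h.evalue <= 1e-5 for h in hits)
        assert all(h.E >= 5.0 for h in hits)
        assert [h.evalue for h in hits] == sorted(h.evalue for h in hits)

    def test_shuffled_query_is_no_hit(self, benchmark, fitted):
        rng = np.random.default_rng(17)
        seq = list(benchmark.domains[0].sequence)
        rng.shuffle(seq)
        assert isinstance(scan("".join(seq), fitted.database_), NoHit)

    def test_no_hit_marker_is_falsy(self):
        assert not NO_HIT


class TestDatabaseRoundTrip:
    def test_jsonl_serialization(self, fitted, tmp_path):
        db = fitted.database_
        path = tmp_path / "db.jsonl"
        db.save(path)
        loaded = ProfileDatabase.load(path)
        assert len(loaded) == len(db)
        for a, b in zip(db.modules, loaded.modules):
            assert a.id == b.id and a.N == b.N
            assert [c.S for c in a.columns] == [c.S for c in b.columns]
            assert [c.C for c in a.columns] == [c.C for c in b.columns]
            np.testing.assert_allclose(a.match_emissions(), b.match_emissions(), atol=1e-8)
        assert loaded.dumps() == db.dumps()
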