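"""Dual-cutoff identification, aggregation identities, decomposition, robustness."""

from fractions import Fraction

import numpy as np
import pytest

import mdpoverty as mp
from mdpoverty.af_core import AFParams, attainable_scores, default_k_grid
from _oracles import af_bruteforce, headcount_at_k

# weights admitting the hand-worked scores {1/2, 1/5, 1/3} as subset sums
TOY_W = (Fraction(1, 2), Fraction(1, 5), Fraction(1, 6), Fraction(2, 15))
TOY_G0 = [
    [1, 0, 0, 0],  # c = 1/2
    [0, 1, 0, 0],  # c = 1/5
    [0, 1, 0, 1],  # c = 1/5 + 2/15 = 1/3
    [0, 0, 0, 0],  # c = 0
]


class TestIdentification:
    def test_toy_scores(self, make_matrix):
        m = make_matrix(TOY_G0, weights=TOY_W)
        c = mp.deprivation_scores(m)
        assert np.allclose(c, [0.5, 0.2, 1 / 3, 0.0])

    def test_inclusive_rule_catches_exact_boundary(self):
        c = np.array([0.5, 0.2, 1 / 3, 0.0])
        poor = mp.identify_poor(c, AFParams(k=Fraction(1, 3), inclusive=True))
        assert poor.tolist() == [1, 0, 1, 0]
        strict = mp.identify_poor(c, AFParams(k=Fraction(1, 3), inclusive=False))
        assert strict.tolist() == [1, 0, 0, 0]

    def test_zero_score_never_poor(self):
        assert mp.identify_poor(np.zeros(4), AFParams(k=Fraction(1, 36))).sum() == 0

    def test_censoring(self):
        c = np.array([0.5, 0.2, 1 / 3, 0.0])
        poor = np.array([1, 0, 1, 0])
        assert np.allclose(mp.censor_scores(c, poor), [0.5, 0, 1 / 3, 0])
        assert np.allclose(mp.censor_scores(c, np.ones(4)), c)
        assert np.allclose(mp.censor_scores(c, np.zeros(4)), 0)

    def test_single_indicator_score_weight(self, make_matrix):
        g0 = np.zeros((1, 11), dtype=int)
        g0[0, 5] = 1  # electricity only
        m = make_matrix(g0)
        assert mp.deprivation_scores(m)[0] == pytest.approx(1 / 18)


class TestAggregation:
    def test_toy_hand_enumeration(self, make_matrix):
        m = make_matrix(TOY_G0, weights=TOY_W)
        res = mp.aggregate(m, compute_ci=False)
        assert res.H == pytest.approx(0.5, abs=1e-15)
        assert res.A == pytest.approx(5 / 12, abs=1e-15)
        assert res.M0 == pytest.approx(5 / 24, abs=1e-15)

    def test_everyone_fully_deprived(self, make_matrix):
        m = make_matrix(np.ones((5, 11), dtype=int))
        res = mp.aggregate(m, compute_ci=False)
        assert (res.H, res.A, res.M0) == (1.0, 1.0, 1.0)

    def test_no_poor_households(self, make_matrix):
        m = make_matrix(np.zeros((5, 11), dtype=int))
        res = mp.aggregate(m, compute_ci=False)
        assert (res.H, res.A, res.M0) == (0.0, 0.0, 0.0)
        assert res.contributions is None  # undefined, not NaN-poisoned

    def test_three_way_identity_on_random_matrices(self, make_matrix):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(5, 60)
            g0 = (rng.random((n, 11)) < rng.random(11)).astype(int)
            s = rng.uniform(0.5, 5.0, n)
            m = make_matrix(g0, s=s)
            res = mp.aggregate(m, compute_ci=False)
            # M0 = H*A = weighted mean censored score = sum_j w_j CH_j
            assert abs(res.M0 - res.H * res.A) < 1e-12
            ws = sum(
                float(w) * ch
                for w, ch in zip(m.weights, res.censored_headcounts.values())
            )
            assert abs(res.M0 - ws) < 1e-12
            assert float(AFParams().k) * res.H <= res.M0 + 1e-12
            assert res.M0 <= res.H + 1e-12
            if res.M0 > 0:
                assert abs(sum(res.contributions.values()) - 1) < 1e-12

    def test_engine_matches_bruteforce_oracle(self, make_matrix):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            raw = rng.integers(1, 10, 11)
            weights = tuple(Fraction(int(x), int(raw.sum())) for x in raw)
            g0 = (rng.random((n, 11)) < rng.random(11)).astype(int)
            s = rng.uniform(0.5, 3.0, n)
            k = Fraction(int(rng.integers(1, 10)), 12)
            m = make_matrix(g0, weights=weights, s=s)
            res = mp.aggregate(m, AFParams(k=k), compute_ci=False)
            ora = af_bruteforce(g0.tolist(), weights, s, k)
            assert abs(res.H - ora["H"]) < 1e-12
            assert abs(res.A - ora["A"]) < 1e-12
            assert abs(res.M0 - ora["M0"]) < 1e-12
            got_ch = list(res.censored_headcounts.values())
            assert np.max(np.abs(np.array(got_ch) - ora["CH"])) < 1e-12


class TestDecomposition:
    def test_single_group_reproduces_overall(self, make_matrix):
        rng = np.random.default_rng(5)
        g0 = (rng.random((30, 11)) < 0.4).astype(int)
        m = make_matrix(g0, s=rng.uniform(1, 2, 30))
        overall = mp.aggregate(m, compute_ci=False)
        dec = mp.subgroup_decomposition(m, ["all"] * 30, compute_ci=False)
        assert dec["all"]["share"] == pytest.approx(1.0)
        assert dec["all"]["result"].M0 == pytest.approx(overall.M0, abs=1e-15)

    def test_identical_groups_have_equal_m0(self, make_matrix):
        g0 = np.tile([[1] * 6 + [0] * 5], (6, 1))
        m = make_matrix(g0)
        dec = mp.subgroup_decomposition(m, ["a", "b"] * 3, compute_ci=False)
        assert dec["a"]["result"].M0 == pytest.approx(dec["b"]["result"].M0)

    def test_shares_recombine_to_pooled_m0(self, make_matrix):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(20, 80))
            g0 = (rng.random((n, 11)) < rng.random(11)).astype(int)
            s = rng.uniform(0.2, 4.0, n)
            labels = rng.choice(["x", "y", "z"], n)
            m = make_matrix(g0, s=s)
            overall = mp.aggregate(m, compute_ci=False)
            dec = mp.subgroup_decomposition(m, labels, compute_ci=False)
            recomb = sum(b["share"] * b["result"].M0 for b in dec.values())
            assert abs(recomb - overall.M0) < 1e-12
            assert sum(b["share"] for b in dec.values()) == pytest.approx(1.0)


class TestRobustness:
    def test_default_grid_has_19_cutoffs_spanning_one_ninth_to_two_thirds(self):
        grid = default_k_grid([s.weight for s in mp.default_indicator_specs()])
        assert len(grid) == 19
        assert grid[0] == Fraction(1, 9)
        assert grid[-1] == Fraction(2, 3)
        assert all(grid[i] < grid[i + 1] for i in range(18))

    def test_attainable_scores_small_case(self):
        got = attainable_scores([Fraction(1, 2), Fraction(1, 4), Fraction(1, 4)])
        assert got == [Fraction(0), Fraction(1, 4), Fraction(1, 2),
                       Fraction(3, 4), Fraction(1)]

    def test_headcount_non_increasing_and_matches_bruteforce(self, make_matrix):
        rng = np.random.default_rng(21)
        for _ in range(5):
            g0 = (rng.random((40, 11)) < rng.random(11)).astype(int)
            s = rng.uniform(0.5, 2.0, 40)
            m = make_matrix(g0, s=s)
            curve = mp.robustness_curve(m, compute_ci=False)
            h = curve["H"].to_numpy()
            assert (np.diff(h) <= 1e-12).all()
            for k_str, h_val in zip(curve["k_exact"], h):
                ora = headcount_at_k(g0.tolist(), m.weights, s, Fraction(k_str))
                assert abs(h_val - ora) < 1e-12

    def test_tiny_cutoff_counts_any_deprivation(self, make_matrix, small_matrix):
        curve = mp.robustness_curve(
            small_matrix, [Fraction(1, 36)], compute_ci=False
        )
        any_dep = (small_matrix.g0.sum(axis=1) > 0).astype(float)
        s = small_matrix.design["sampling_weight"].to_numpy()
        assert curve["H"].iloc[0] == pytest.approx(np.average(any_dep, weights=s))
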