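"""EA aggregation, variogram estimation/fitting, ordinary kriging."""

import numpy as np
import pandas as pd
import pytest

import mdpoverty as mp
from mdpoverty.errors import ValidationError
from mdpoverty.geo import VariogramModel, ok_weights, semivariance


def ea_frame(pts, vals):
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "m0": vals})


class TestAggregateByEA:
    def test_single_ea_equals_overall_m0(self, make_matrix):
        rng = np.random.default_rng(0)
        g0 = (rng.random((20, 11)) < 0.5).astype(int)
        m = make_matrix(g0, ea=["onlyea"] * 20)
        overall = mp.aggregate(m, compute_ci=False)
        est = mp.aggregate_by_ea(m)
        assert len(est) == 1
        assert est["m0"].iloc[0] == pytest.approx(overall.M0, abs=1e-15)

    def test_nonpoor_ea_has_zero_m0(self, make_matrix):
        g0 = np.vstack([np.zeros((5, 11), int), np.ones((5, 11), int)])
        m = make_matrix(g0, ea=["a"] * 5 + ["b"] * 5)
        est = mp.aggregate_by_ea(m).set_index("ea_id")
        assert est.loc["a", "m0"] == 0.0
        assert est.loc["b", "m0"] == 1.0

    def test_weighted_ea_values_recombine_to_overall(self, small_matrix):
        overall = mp.aggregate(small_matrix, compute_ci=False)
        est = mp.aggregate_by_ea(small_matrix)
        recomb = np.sum(est["weight"] * est["m0"]) / est["weight"].sum()
        assert recomb == pytest.approx(overall.M0, abs=1e-12)


class TestEmpiricalVariogram:
    def test_constant_field_gives_zero_semivariance(self):
        pts = np.random.default_rng(0).random((30, 2)) * 10
        emp = mp.empirical_variogram(pts, np.full(30, 0.4))
        assert (emp["gamma"] == 0).all()

    def test_two_points_single_pair_definition(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        emp = mp.empirical_variogram(pts, np.array([1.0, 4.0]), n_bins=1, max_dist=10)
        assert len(emp) == 1
        assert emp["gamma"].iloc[0] == pytest.approx((1.0 - 4.0) ** 2 / 2)
        assert emp["n_pairs"].iloc[0] == 1

    def test_coincident_points_rejected(self):
        with pytest.raises(ValidationError):
            mp.empirical_variogram(np.zeros((5, 2)), np.arange(5.0))


class TestFitVariogram:
    @pytest.mark.parametrize("family", ["exponential", "spherical", "gaussian"])
    def test_noiseless_self_consistency(self, family):
        truth = VariogramModel(family, nugget=0.2, partial_sill=1.3, range_param=4.0)
        d = np.linspace(0.5, 12, 20)
        emp = pd.DataFrame(
            {"dist": d, "gamma": semivariance(truth, d), "n_pairs": 50}
        )
        fit = mp.fit_variogram(emp, family)
        assert fit.nugget == pytest.approx(truth.nugget, abs=1e-6)
        assert fit.partial_sill == pytest.approx(truth.partial_sill, abs=1e-6)
        assert fit.range_param == pytest.approx(truth.range_param, abs=1e-5)

    def test_flat_semivariogram_falls_back_to_nugget_only(self):
        emp = pd.DataFrame(
            {"dist": [1.0, 2.0, 3.0, 4.0], "gamma": [0.5] * 4, "n_pairs": [10] * 4}
        )
        with pytest.warns(UserWarning):
            fit = mp.fit_variogram(emp)
        assert fit.partial_sill == 0.0
        assert fit.nugget == pytest.approx(0.5, rel=0.05)

    def test_too_few_bins_rejected(self):
        emp = pd.DataFrame({"dist": [1.0, 2.0], "gamma": [0.1, 0.2], "n_pairs": [5, 5]})
        with pytest.raises(ValidationError):
            mp.fit_variogram(emp)


class TestKrige:
    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.random((40, 2)) * 10
        model = VariogramModel("exponential", 0.1, 1.0, 3.0)
        lam, mu, _ = ok_weights(pts, model, rng.random((25, 2)) * 10)
        assert np.max(np.abs(lam.sum(axis=1) - 1.0)) < 1e-8

    def test_exact_interpolation_with_zero_nugget(self):
        rng = np.random.default_rng(3)
        pts = rng.random((25, 2)) * 10
        vals = rng.random(25)
        model = VariogramModel("exponential", 0.0, 1.0, 3.0)
        surf = mp.krige(ea_frame(pts, vals), model, pts)
        assert np.max(np.abs(surf.grid["m0_pred"].to_numpy() - vals)) < 1e-8
        assert (surf.grid["ok_variance"].to_numpy() < 1e-8).all()

    def test_constant_field_reproduced_everywhere(self):
        rng = np.random.default_rng(4)
        pts = rng.random((15, 2)) * 5
        for family in ("exponential", "spherical", "gaussian"):
            model = VariogramModel(family, 0.2, 0.8, 2.0)
            surf = mp.krige(ea_frame(pts, np.full(15, 0.31)), model, (8, 8))
            assert np.allclose(surf.grid["m0_pred"], 0.31, atol=1e-9)

    def test_symmetric_midpoint_is_average_of_two_points(self):
        # hand-solvable 2x2 system: equal semivariances force lambda = (1/2, 1/2)
        pts = np.array([[0.0, 0.0], [4.0, 0.0]])
        vals = np.array([0.2, 0.8])
        model = VariogramModel("exponential", 0.0, 1.0, 2.0)
        surf = mp.krige(ea_frame(pts, vals), model, np.array([[2.0, 0.0]]))
        assert surf.grid["m0_pred"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_variance_nonnegative_and_clamped_column(self):
        rng = np.random.default_rng(5)
        pts = rng.random((30, 2)) * 10
        vals = rng.random(30)
        model = VariogramModel("exponential", 0.05, 0.5, 2.0)
        surf = mp.krige(ea_frame(pts, vals), model, (10, 10))
        assert (surf.grid["ok_variance"] >= 0).all()
        assert surf.grid["m0_pred_clamped"].between(0, 1).all()

    def test_kriging_beats_global_mean_on_smooth_field(self):
        # hold-out prediction error vs. the constant predictor, 3 replicates
        wins = 0
        for rep in range(3):
            rng = np.random.default_rng(60 + rep)
            pts = rng.random((120, 2)) * 20
            z = mp.spatial_latent_field(pts, 5.0, 1.0, 600 + rep)
            train, test = slice(0, 90), slice(90, None)
            emp = mp.empirical_variogram(pts[train], z[train], n_bins=12)
            model = mp.fit_variogram(emp)
            surf = mp.krige(ea_frame(pts[train], z[train]), model, pts[test])
            rmse_k = np.sqrt(np.mean((surf.grid["m0_pred"].to_numpy() - z[test]) ** 2))
            rmse_m = np.sqrt(np.mean((z[train].mean() - z[test]) ** 2))
            wins += rmse_k < rmse_m
        assert wins == 3
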