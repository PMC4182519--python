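"""Synthetic survey generator: determinism, calibration, spatial structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

import mdpoverty as mp
from mdpoverty.errors import ConfigError, ValidationError
from mdpoverty.synth import DEFAULT_TARGET_MARGINALS, _sample_threshold


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_tables(self):
        cfg = mp.SimConfig(n_eas=20, households_per_ea=5, seed=123)
        a = mp.generate_survey(cfg)
        b = mp.generate_survey(cfg)
        assert a.households.to_csv(index=False) == b.households.to_csv(index=False)
        assert a.eas.to_csv(index=False) == b.eas.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = mp.generate_survey(mp.SimConfig(n_eas=20, households_per_ea=5, seed=1))
        b = mp.generate_survey(mp.SimConfig(n_eas=20, households_per_ea=5, seed=2))
        assert not a.households.equals(b.households)


@pytest.fixture(scope="module")
def survey3000():
    return mp.generate_survey(mp.SimConfig(n_eas=200, households_per_ea=15, seed=11))


class TestCalibration:
    def test_marginals_within_four_monte_carlo_ses(self, survey3000):
        m = mp.build_deprivation_matrix(survey3000.households)
        n = m.n
        obs = m.g0.mean(axis=0)
        for o, p in zip(obs, DEFAULT_TARGET_MARGINALS):
            se = np.sqrt(max(p * (1 - p), 1e-6) / n)
            assert abs(o - p) <= 4 * se

    def test_electricity_marginal_close(self, survey3000):
        elec_dep = 1 - survey3000.households["electricity"].to_numpy()
        assert abs(elec_dep.mean() - 0.951) <= 0.015

    def test_zero_marginals_mean_no_deprivations(self):
        cfg = mp.SimConfig(
            n_eas=10, households_per_ea=5, target_marginals=(0.0,) * 11, seed=3
        )
        m = mp.build_deprivation_matrix(mp.generate_survey(cfg).households)
        assert m.g0.sum() == 0

    def test_income_zero_fraction(self, survey3000):
        inc = survey3000.households["monthly_income_mzn"].to_numpy()
        p0 = 0.49
        se = np.sqrt(p0 * (1 - p0) / len(inc))
        assert abs((inc == 0).mean() - p0) <= 3 * se

    def test_rural_fraction_and_district_allocation(self, survey3000):
        eas = survey3000.eas
        assert (eas["urban"] == 1).sum() == round(0.04 * 200)
        assert set(eas["district"]) == {d for d, _ in mp.synth.DEFAULT_DISTRICTS}

    def test_indicators_independent_without_clustering(self):
        # sill 0 and one household per EA: indicator columns are iid draws
        cfg = mp.SimConfig(
            n_eas=2000, households_per_ea=1, latent_sill=0.0, seed=5
        )
        m = mp.build_deprivation_matrix(mp.generate_survey(cfg).households)
        col = m.g0[:, 10].astype(float)  # low assets, p ~ 0.43
        r = np.corrcoef(col[:-1], col[1:])[0, 1]
        assert abs(r) <= 3 / np.sqrt(len(col) - 1)

    def test_urban_households_less_poor(self):
        # urban latent advantage: urban headcount well below rural
        cfg = mp.SimConfig(n_eas=150, households_per_ea=10, rural_fraction=0.7, seed=9)
        tables = mp.generate_survey(cfg)
        m = mp.build_deprivation_matrix(tables.households)
        poor = mp.identify_poor(mp.deprivation_scores(m))
        urban = tables.households["urban"].to_numpy()
        assert poor[urban == 1].mean() < poor[urban == 0].mean() - 0.1

    def test_wealth_latent_aligned_with_poverty(self, survey3000):
        # asset ownership should be scarcer among the multidimensionally poor
        hh = survey3000.households
        m = mp.build_deprivation_matrix(hh)
        poor = mp.identify_poor(mp.deprivation_scores(m)).astype(bool)
        owned = hh[[c for c in hh.columns if c.startswith("asset_")]].sum(axis=1)
        assert owned[poor].mean() < owned[~poor].mean()

    def test_sampling_probabilities_valid(self, survey3000):
        p = survey3000.households["sampling_probability"].to_numpy()
        assert ((p > 0) & (p <= 1)).all()

    def test_population_calibration_unbiased_in_expectation(self):
        # average marginals over seeds approach targets under fixed thresholds
        obs = np.zeros(11)
        reps = 8
        for seed in range(reps):
            cfg = mp.SimConfig(
                n_eas=100, households_per_ea=10, calibration="population", seed=seed
            )
            m = mp.build_deprivation_matrix(mp.generate_survey(cfg).households)
            obs += m.g0.mean(axis=0)
        obs /= reps
        assert np.max(np.abs(obs - np.array(DEFAULT_TARGET_MARGINALS))) < 0.04


class TestThresholds:
    def test_median_threshold_is_zero(self):
        assert mp.calibrate_threshold(0.5, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_inverse_normal_cdf(self):
        assert mp.calibrate_threshold(0.951, 0.0) == pytest.approx(ndtri(0.951))
        assert mp.calibrate_threshold(0.3, 1.0) == pytest.approx(
            np.sqrt(2.0) * ndtri(0.3)
        )

    def test_degenerate_rates_use_sentinels(self):
        assert mp.calibrate_threshold(0.0, 0.5) == -np.inf
        assert mp.calibrate_threshold(1.0, 0.5) == np.inf

    def test_sample_threshold_hits_realized_rate(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 0.6, 500)
        from scipy.special import ndtr

        t = _sample_threshold(0.3, z)
        assert np.mean(ndtr(t - z)) == pytest.approx(0.3, abs=1e-10)


class TestSpatialField:
    def test_zero_sill_returns_zeros(self):
        pts = np.random.default_rng(0).random((10, 2))
        assert (mp.spatial_latent_field(pts, 5.0, 0.0, 1) == 0).all()

    def test_coincident_points_share_values(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 4.0]])
        z = mp.spatial_latent_field(pts, 2.0, 1.0, 7)
        assert z[0] == z[1]

    def test_short_range_decorrelates(self):
        # replicate draws at two fixed nearby points; correlation ~ 0
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        reps = 400
        draws = np.array(
            [mp.spatial_latent_field(pts, 1e-6, 1.0, s) for s in range(reps)]
        )
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(r) <= 3 / np.sqrt(reps)

    def test_long_range_correlates(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        draws = np.array(
            [mp.spatial_latent_field(pts, 1e6, 1.0, s) for s in range(200)]
        )
        assert np.corrcoef(draws[:, 0], draws[:, 1])[0, 1] > 0.95

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            mp.spatial_latent_field(np.array([[0.0, np.inf]]), 1.0, 1.0, 0)


class TestExpectedHeadcount:
    def test_single_indicator_reduces_to_marginal(self):
        from fractions import Fraction

        h = mp.expected_headcount([Fraction(1)], [0.37], 0.0, k=Fraction(1, 2))
        assert h == pytest.approx(0.37, abs=1e-9)

    def test_matches_monte_carlo_without_clustering(self):
        from fractions import Fraction

        w = [s.weight for s in mp.default_indicator_specs()]
        h = mp.expected_headcount(w, DEFAULT_TARGET_MARGINALS, 0.0)
        rng = np.random.default_rng(1)
        n = 200_000
        t = np.array([ndtri(p) for p in DEFAULT_TARGET_MARGINALS])
        dep = rng.standard_normal((n, 11)) < t[None, :]
        wn = np.array([int(Fraction(x) * 36) for x in w])
        mc = float(((dep @ wn) * 3 >= 36).mean())
        assert abs(h - mc) <= 4 * np.sqrt(h * (1 - h) / n)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_eas", 1),
            ("households_per_ea", 0),
            ("rural_fraction", 1.5),
            ("target_marginals", (0.5,) * 10),
            ("latent_sill", -0.1),
            ("income_zero_fraction", -0.2),
            ("calibration", "magic"),
            ("ea_bbox", (0, 0, 0, 10)),
        ],
    )
    def test_invalid_config_names_the_field(self, field, value):
        cfg = mp.SimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            mp.generate_survey(cfg)
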