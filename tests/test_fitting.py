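"""Least-squares estimation: recovery, oracles, nesting, summaries."""

import numpy as np
import pandas as pd
import pytest

import weedcomp as wc
from weedcomp.exceptions import (
    DesignError,
    UndefinedStatisticError,
    UnstableFitWarning,
)
from weedcomp.fitting import select_levels

from _oracles import grid_search_hyperbola_rss, normal_equation_coefs

TRUTH = wc.DEFAULT_TRUTH["late_watergrass"]


def hyperbola_design(y0, beta, densities=(0, 20, 40, 80, 160), reps=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.repeat(densities, reps).astype(float)
    y = y0 / (1 + beta * x) + rng.normal(0, noise, x.size)
    return x, y


class TestRectangularHyperbola:
    def test_noise_free_recovery(self):
        x, y = hyperbola_design(5.0, 0.01)
        est = wc.RectangularHyperbola().fit(x[:, None], y)
        assert est.y0_ == pytest.approx(5.0, abs=1e-6)
        assert est.beta_ == pytest.approx(0.01, abs=1e-6)
        assert est.rss_ == pytest.approx(0.0, abs=1e-12)
        assert est.pseudo_r2_ == pytest.approx(1.0)

    def test_flat_data(self):
        x = np.repeat([0, 20, 40, 80], 3).astype(float)
        y = np.full(x.size, 5.0)
        est = wc.RectangularHyperbola().fit(x[:, None], y)
        assert est.y0_ == pytest.approx(5.0, abs=1e-8)
        assert est.beta_ == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        x, y = hyperbola_design(5.2, 0.015, densities=(0, 10, 20, 40, 80), noise=0.4, seed=5)
        est = wc.RectangularHyperbola().fit(x[:, None], y)
        oracle = grid_search_hyperbola_rss(x, y)
        assert est.rss_ == pytest.approx(oracle, abs=1e-6)

    def test_single_density_rejected(self):
        x = np.full(6, 40.0)
        with pytest.raises(DesignError):
            wc.RectangularHyperbola().fit(x[:, None], x)

    def test_predict_roundtrip(self):
        x, y = hyperbola_design(5.0, 0.01)
        est = wc.RectangularHyperbola().fit(x[:, None], y)
        np.testing.assert_allclose(est.predict(x[:, None]), y, atol=1e-6)

    def test_collapsed_level_flags_unstable_beta(self):
        # near-zero yields with noise comparable to signal: wide-SE warning
        rng = np.random.default_rng(2)
        x = np.repeat([0, 20, 40, 80, 160], 3).astype(float)
        y = np.clip(0.23 / (1 + 0.08 * x) + rng.normal(0, 0.12, x.size), 0, None)
        with pytest.warns(UnstableFitWarning):
            wc.RectangularHyperbola().fit(x[:, None], y)

    def test_sklearn_params_roundtrip(self):
        est = wc.RectangularHyperbola(n_starts=3)
        assert est.get_params()["n_starts"] == 3
        est.set_params(n_starts=4)
        assert est.n_starts == 4


class TestPerLevelPooled:
    def test_single_level_reduces_to_hyperbola(self, noise_free_trial):
        obs, _, _ = noise_free_trial
        one = obs[(obs["year"] == 2014) & (obs["regime"] == "A")]
        pooled = wc.fit_per_level_pooled(one)
        single = wc.fit_hyperbola(one)
        assert pooled.rss == pytest.approx(single.rss, abs=1e-12)
        assert pooled.n_params == 2

    def test_pooled_rss_is_sum_of_levels(self, noisy_trial):
        obs, _, _ = noisy_trial
        X = obs[["gdd_flowering", "density"]].to_numpy()
        y = obs["yield_t_ha"].to_numpy()
        levels = list(zip(obs["year"], obs["regime"]))
        est = wc.PerLevelHyperbola().fit(X, y, levels=levels)
        assert est.rss_ == pytest.approx(est.params_["rss"].sum(), rel=1e-12)
        assert est.n_params_ == 2 * len(est.levels_)
        assert est.df_resid_ == est.n_obs_ - est.n_params_

    def test_level_inclusion_rule_drops_collapsed_levels(self, heatwave_trial):
        # hot-year sterility collapses the two hottest regimes: 12 -> 10 levels
        obs, _, _ = heatwave_trial
        lw = obs[obs["species"] == "late_watergrass"]
        kept = select_levels(lw, min_weed_free_yield=1.0)
        kept_levels = kept.groupby(["year", "regime"]).ngroups
        assert kept_levels == 10
        with pytest.warns(UnstableFitWarning):
            pooled_all = wc.fit_per_level_pooled(lw, min_weed_free_yield=0.0)
        assert pooled_all.n_params == 24
        pooled = wc.fit_per_level_pooled(lw)
        assert pooled.n_params == 20


class TestJointFits:
    def test_intermediate_noise_free_consistency(self, noise_free_trial):
        obs, levels, _ = noise_free_trial
        res = wc.fit_intermediate(obs)
        assert res.n_params == 3 + 12
        for key, tv in zip("abc", (TRUTH.a, TRUTH.b, TRUTH.c)):
            assert res.params[key] == pytest.approx(tv, rel=1e-4)
        for _, lev in levels.iterrows():
            beta_key = f"beta[{(lev['year'], lev['regime'])}]"
            expected = TRUTH.l + TRUTH.m * lev["gdd_flowering"]
            assert res.params[beta_key] == pytest.approx(expected, rel=1e-3)

    def test_combined_noise_free_recovery(self, noise_free_trial):
        obs, _, _ = noise_free_trial
        res = wc.fit_combined(obs)
        assert res.n_params == 5
        for key, tv in zip("abclm", TRUTH.as_tuple()):
            assert res.params[key] == pytest.approx(tv, rel=1e-4)

    def test_nesting_rss_ordering(self, noisy_trial):
        obs, _, _ = noisy_trial
        full = wc.fit_per_level_pooled(obs)
        inter = wc.fit_intermediate(obs)
        comb = wc.fit_combined(obs)
        assert comb.rss >= inter.rss - 1e-8
        assert inter.rss >= full.rss - 1e-8

    def test_too_few_levels_rejected(self, noisy_trial):
        obs, _, _ = noisy_trial
        sub = obs[(obs["year"] == 2014) & (obs["regime"].isin(["A", "A+1.5"]))]
        with pytest.raises(DesignError):
            wc.fit_intermediate(sub)

    def test_mixed_species_rejected(self, heatwave_trial):
        obs, _, _ = heatwave_trial
        with pytest.raises(DesignError):
            wc.fit_combined(obs)


class TestStage2:
    def test_quadratic_exact_parabola(self):
        gdd = np.array([1300.0, 1500.0, 1700.0, 1900.0, 2100.0])
        y0 = -16.0 + 0.03 * gdd - 1e-5 * gdd**2
        res = wc.fit_stage2_quadratic(gdd, y0)
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        assert res.pseudo_r2 == pytest.approx(1.0)
        assert res.params["a"] == pytest.approx(-16.0, rel=1e-6)

    def test_quadratic_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        gdd = np.linspace(1250, 2100, 12)
        y0 = 5 + rng.normal(0, 0.5, gdd.size)
        res = wc.fit_stage2_quadratic(gdd, y0)
        design = np.column_stack([np.ones_like(gdd), gdd, gdd**2])
        a, b, c = normal_equation_coefs(design, y0)
        assert res.params["a"] == pytest.approx(a, rel=1e-6)
        assert res.params["b"] == pytest.approx(b, rel=1e-6)
        assert res.params["c"] == pytest.approx(c, rel=1e-6)

    def test_linear_collinear_points_exact(self):
        gdd = np.array([1300.0, 1500.0, 1700.0])
        beta = -0.021 + 2e-5 * gdd
        res = wc.fit_stage2_linear(gdd, beta)
        assert res.params["l"] == pytest.approx(-0.021, rel=1e-9)
        assert res.params["m"] == pytest.approx(2e-5, rel=1e-9)
        assert res.rss == pytest.approx(0.0, abs=1e-15)

    def test_linear_matches_covariance_formula(self):
        rng = np.random.default_rng(9)
        gdd = np.linspace(1250, 2100, 12)
        beta = 0.005 + rng.normal(0, 0.003, gdd.size)
        res = wc.fit_stage2_linear(gdd, beta)
        slope = np.cov(gdd, beta, ddof=1)[0, 1] / np.var(gdd, ddof=1)
        assert res.params["m"] == pytest.approx(slope, rel=1e-9)

    def test_slope_positive_on_trial_like_inputs(self, noisy_trial):
        obs, _, _ = noisy_trial
        tab = wc.per_level_table(obs)
        res = wc.fit_stage2_linear(tab["gdd"], tab["beta"])
        assert res.params["m"] > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(DesignError):
            wc.fit_stage2_quadratic([1, 2, 3], [1, 2, 3])
        with pytest.raises(DesignError):
            wc.fit_stage2_linear([1, 2], [1, 2])


class TestSummaryStatistics:
    def test_pseudo_r2_limits(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        tss = np.sum((y - y.mean()) ** 2)
        assert wc.pseudo_r2(0.0, y) == 1.0
        assert wc.pseudo_r2(tss, y) == pytest.approx(0.0)
        assert wc.pseudo_r2(2 * tss, y) < 0  # worse than the mean is allowed

    def test_pseudo_r2_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            wc.pseudo_r2(1.0, np.full(5, 2.0))

    def test_rms_examples(self):
        assert wc.rms(0.0, 7) == 0.0
        assert wc.rms(4.0, 4) == 1.0
        with pytest.raises(UndefinedStatisticError):
            wc.rms(1.0, 0)

    def test_default_simulator_rms_in_plausible_band(self, noisy_trial):
        # per-level RMS magnitudes bracket the 0.12-0.97 t/ha scale of
        # phytotron pot trials when sigma = 0.5
        obs, _, _ = noisy_trial
        tab = wc.per_level_table(obs)
        assert tab["rms"].between(0.3, 0.9).mean() >= 0.8
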