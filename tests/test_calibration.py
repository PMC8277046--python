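"""Calibration: initial-state estimation, CIs, and parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest

from glucodyn import (
    CalibrationConfig,
    Cohort,
    KineticParameters,
    SystemState,
    TimeCoursePair,
    estimate_initial_state,
    confidence_intervals,
    fit_global,
    fit_local,
    fit_mixed,
    simulate,
)
from glucodyn.calibrate import NonIdentifiableError
from glucodyn.model import default_grid


def make_pair(params, n0=30.0, d0=0.5, g0=1.0, noise=None, seed=0, well="w1"):
    tr = simulate(SystemState(n0, d0, g0), params, 2, default_grid())
    live, dead = tr.live, tr.dead
    if noise is not None:
        rng = np.random.default_rng(seed)
        live = np.maximum(live * (1 + rng.normal(0, noise[0], live.shape)), 0)
        dead = np.maximum(dead * (1 + rng.normal(0, noise[1], dead.shape)), 0)
    return TimeCoursePair(well_id=well, n0_pct=n0, g0_mm=g0, times=tr.times,
                          live=live, dead=dead)


TRUE = KineticParameters(k_p=0.092, k_d=0.13, k_bys=0.6, v=2.68e-5)


class TestInitialState:
    def test_mean_of_first_three(self):
        pair = TimeCoursePair("w", 12.0, 1.0, np.arange(5.0),
                              np.array([10.0, 12.0, 14.0, 15.0, 16.0]),
                              np.array([1.0, 1.0, 1.0, 2.0, 2.0]))
        est = estimate_initial_state(pair)
        assert est.n0 == 12.0
        assert est.d0 == 1.0

    def test_constant_series(self):
        pair = TimeCoursePair("w", 7.0, 1.0, np.arange(4.0),
                              np.full(4, 7.0), np.full(4, 0.3))
        est = estimate_initial_state(pair)
        assert est.n0 == 7.0 and est.d0 == pytest.approx(0.3)
        assert est.n0_se == 0.0

    def test_close_to_truth_on_noise_free_pair(self):
        pair = make_pair(TRUE)
        est = estimate_initial_state(pair)
        increment = abs(pair.live[1] - pair.live[0])
        assert abs(est.n0 - 30.0) <= max(increment, 0.5)

    def test_too_short(self):
        pair = TimeCoursePair("w", 1.0, 1.0, [0.0, 1.0], [1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            estimate_initial_state(pair)


class TestConfidenceIntervals:
    def test_zero_residuals_zero_width(self, rng):
        J = rng.normal(size=(20, 3))
        half = confidence_intervals(np.zeros(20), J)
        assert np.allclose(half, 0.0)

    def test_matches_ols_closed_form(self, rng):
        # straight-line regression oracle via statsmodels
        import statsmodels.api as sm

        x = np.linspace(0, 1, 30)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.1, 30)
        X = sm.add_constant(x)
        fitted = sm.OLS(y, X).fit()
        expected_half = (fitted.conf_int(alpha=0.05)[:, 1] - fitted.params)
        half = confidence_intervals(y - fitted.fittedvalues, X)
        assert np.allclose(half, expected_half, rtol=1e-8)

    def test_rank_deficient_raises(self):
        J = np.ones((10, 2))  # two identical columns
        with pytest.raises(NonIdentifiableError):
            confidence_intervals(np.ones(10) * 0.1, J)


class TestFitLocal:
    def test_noise_free_recovery(self, fast_config):
        pair = make_pair(TRUE)
        fit = fit_local(pair, 2, fast_config)
        for name, truth in (("k_p", 0.092), ("k_d", 0.13), ("k_bys", 0.6), ("v", 2.68e-5)):
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-3), name
        assert fit.rss < 1e-3

    def test_nested_variants_without_bystander_truth(self, fast_config):
        p0 = replace(TRUE, k_bys=0.0)
        pair = make_pair(p0, noise=(0.02, 0.05), seed=5)
        cfg = replace(fast_config, weighting="none")
        f1 = fit_local(pair, 1, cfg)
        f2 = fit_local(pair, 2, cfg)
        assert f2.estimates["k_bys"] == pytest.approx(0.0, abs=2e-2)
        assert f2.rss <= f1.rss * 1.001
        assert f1.rss == pytest.approx(f2.rss, rel=0.01)

    def test_nested_objective_ordering(self, fast_config):
        pair = make_pair(TRUE, g0=0.5, noise=(0.05, 0.15), seed=6)
        cfg = replace(fast_config, weighting="none")
        f1 = fit_local(pair, 1, cfg)
        f2 = fit_local(pair, 2, cfg)
        f3 = fit_local(pair, 3, cfg)
        assert f2.objective <= f1.objective * (1 + 1e-6)
        assert f2.objective <= f3.objective * (1 + 1e-6)

    def test_multistart_reproducible_optimum(self):
        pair = make_pair(TRUE, noise=(0.069, 0.31), seed=11)
        a = fit_local(pair, 2, CalibrationConfig(n_starts=10, seed=1))
        b = fit_local(pair, 2, CalibrationConfig(n_starts=10, seed=99))
        assert a.objective == pytest.approx(b.objective, rel=1e-6)


class TestFitGlobalAndMixed:
    def test_global_on_identical_pairs_equals_local(self, fast_config):
        pair = make_pair(TRUE)
        cohort = Cohort("c", [pair, TimeCoursePair("w2", 30.0, 1.0, pair.times,
                                                   pair.live.copy(), pair.dead.copy())])
        g = fit_global(cohort, 2, fast_config)
        l = fit_local(pair, 2, fast_config)
        for name in g.estimates:
            assert g.estimates[name] == pytest.approx(l.estimates[name], rel=1e-3)

    def test_global_rss_bounds_sum_of_local(self, bt_cohort_noisy, fast_config):
        cfg = replace(fast_config, weighting="none")
        g = fit_global(bt_cohort_noisy, 2, cfg)
        locals_ = [fit_local(p, 2, cfg) for p in bt_cohort_noisy]
        assert g.rss >= sum(f.rss for f in locals_) * (1 - 1e-9)

    def test_mixed_recovers_shared_rates_noise_free(self, bt_cohort_noisefree, fast_config):
        fit = fit_mixed(bt_cohort_noisefree, 2, fast_config)
        assert fit.shared.estimates["k_p"] == pytest.approx(0.092, rel=1e-3)
        assert fit.shared.estimates["k_d"] == pytest.approx(0.13, rel=1e-3)
        assert fit.shared.estimates["v"] == pytest.approx(2.68e-5, rel=1e-3)
        kb = fit.k_bys_table()["k_bys"].to_numpy()
        kt = np.array([p.k_bys_true for p in bt_cohort_noisefree])
        assert np.max(np.abs(kb - kt) / kt) < 1e-2

    def test_mixed_kbys_tracks_generating_law_under_noise(self, bt_profile, tiny_design, fast_config):
        from glucodyn import generate_cohort

        cohort = generate_cohort(bt_profile, tiny_design, seed=77)
        fit = fit_mixed(cohort, 2, fast_config)
        kb = fit.k_bys_table()["k_bys"].to_numpy()
        kt = np.array([p.k_bys_true for p in cohort])
        assert np.corrcoef(kb, kt)[0, 1] > 0.9

    def test_single_pair_mixed_equals_local(self, fast_config):
        pair = make_pair(TRUE, noise=(0.02, 0.05), seed=3)
        mixed = fit_mixed(Cohort("c", [pair]), 2, fast_config)
        local = fit_local(pair, 2, fast_config)
        assert mixed.objective == pytest.approx(local.objective, rel=1e-4)
        assert mixed.shared.estimates["k_p"] == pytest.approx(
            local.estimates["k_p"], rel=1e-2
        )

    def test_high_glucose_wells_have_small_similar_kbys(self, mda_profile, fast_config):
        from glucodyn import CohortDesign, generate_cohort

        # MDA-like line at saturating glucose: law floor (beta) everywhere
        design = CohortDesign(glucose_levels_mm=(8.0, 10.0), tiers_pct=(37.0, 72.0),
                              replicates=1, k_bys_lognorm_sigma=0.0,
                              n0_jitter_sd_pct=0.0, d0_jitter_sd_pct=0.0)
        cohort = generate_cohort(mda_profile, design, seed=21)
        fit = fit_mixed(cohort, 2, fast_config)
        kb = fit.k_bys_table()["k_bys"].to_numpy()
        assert np.all(kb < 0.6)
        assert kb.std() / kb.mean() < 0.6
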