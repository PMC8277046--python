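"""Train/validate machinery: splits, bands, accuracy, and error metrics."""

import numpy as np
import pytest

from glucodyn import (
    BystanderLaw,
    CalibrationConfig,
    Cohort,
    CohortDesign,
    FitResult,
    accuracy,
    evaluate,
    fit_mixed,
    generate_cohort,
    predict,
    run_rounds,
    split_cohort,
    training_uncertainty,
)
from glucodyn.validate import PredictionBand, _fit_law_from_mixed


class TestSplit:
    def test_default_fraction_partitions_120_into_90_30(self, bt_profile):
        cohort = generate_cohort(bt_profile, CohortDesign(), seed=1)
        plan = split_cohort(cohort, seed=4)
        assert len(plan.train_ids) == 90
        assert len(plan.validation_ids) == 30
        union = set(plan.train_ids) | set(plan.validation_ids)
        assert union == set(range(120))
        assert not set(plan.train_ids) & set(plan.validation_ids)

    def test_seeded_and_deterministic(self, bt_cohort_noisy):
        a = split_cohort(bt_cohort_noisy, seed=7)
        b = split_cohort(bt_cohort_noisy, seed=7)
        assert a.train_ids == b.train_ids
        c = split_cohort(bt_cohort_noisy, seed=8)
        assert a.train_ids != c.train_ids

    def test_fraction_bounds(self, bt_cohort_noisy):
        with pytest.raises(ValueError):
            split_cohort(bt_cohort_noisy, fraction=1.0)
        with pytest.raises(ValueError):
            split_cohort(bt_cohort_noisy, fraction=0.0)


def make_band(times, live, dead, half=0.0):
    return PredictionBand(
        times=times,
        live_mean=live, live_lo=live - half, live_hi=live + half,
        dead_mean=dead, dead_lo=np.maximum(dead - half, 0), dead_hi=dead + half,
        n_draws=1000,
    )


class TestAccuracy:
    def test_full_coverage(self):
        t = np.arange(5.0)
        live = np.full(5, 10.0)
        band = make_band(t, live, live, half=1.0)
        pair = _pair(t, live, live)
        assert accuracy(band, pair) == (1.0, 1.0)

    def test_zero_width_band_off_data(self):
        t = np.arange(5.0)
        band = make_band(t, np.full(5, 10.0), np.full(5, 10.0), half=0.0)
        pair = _pair(t, np.full(5, 11.0), np.full(5, 12.0))
        assert accuracy(band, pair) == (0.0, 0.0)

    def test_counting(self):
        t = np.arange(33.0)
        live = np.zeros(33)
        live[:17] = 0.5  # 17 of 33 inside [0, 1]
        live[17:] = 5.0
        band = make_band(t, np.full(33, 0.5), np.full(33, 0.5), half=0.5)
        pair = _pair(t, live, np.full(33, 0.5))
        a_live, a_dead = accuracy(band, pair)
        assert a_live == pytest.approx(17 / 33)
        assert a_dead == 1.0

    def test_monotone_under_band_widening(self, rng):
        t = np.arange(20.0)
        data = 10 + rng.normal(0, 2, 20)
        pair = _pair(t, data, data)
        center = np.full(20, 10.0)
        prev = -1.0
        for half in (0.5, 1.0, 2.0, 4.0, 8.0):
            band = make_band(t, center, center, half=half)
            a, _ = accuracy(band, pair)
            assert a >= prev
            prev = a

    def test_grid_mismatch(self):
        band = make_band(np.arange(5.0), np.ones(5), np.ones(5))
        pair = _pair(np.arange(4.0), np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            accuracy(band, pair)


def _pair(t, live, dead, well="w", n0=10.0, g0=1.0):
    from glucodyn import TimeCoursePair

    return TimeCoursePair(well_id=well, n0_pct=n0, g0_mm=g0, times=t,
                          live=np.asarray(live, float), dead=np.asarray(dead, float))


class TestEvaluate:
    def test_perfect_model_all_zero(self):
        d = np.array([[1.0, 2.0, 3.0]])
        rep = evaluate(d, d, d, d)
        for s in (rep.live, rep.dead):
            assert s.rss == 0 and s.mean_pct_error == 0 and s.mean_error == 0
            assert s.pct_error_eoe == 0 and s.error_eoe == 0

    def test_ten_percent_inflation(self):
        d = np.array([[10.0, 20.0, 30.0]])
        rep = evaluate(1.1 * d, d, 1.1 * d, d)
        assert rep.live.mean_pct_error == pytest.approx(10.0)
        assert rep.live.pct_error_eoe == pytest.approx(10.0)
        assert rep.live.mean_error == pytest.approx(2.0)  # mean of 1,2,3
        assert rep.live.error_eoe == pytest.approx(3.0)

    def test_zero_data_points_excluded_and_counted(self):
        d = np.array([[0.0, 10.0]])
        m = np.array([[1.0, 11.0]])
        rep = evaluate(m, d, m, d)
        assert rep.live.n_zero_excluded == 1
        assert rep.live.mean_pct_error == pytest.approx(10.0)

    def test_matches_spreadsheet_oracle_two_wells(self):
        # independent brute-force metric computation
        data = np.array([[10.0, 20.0, 40.0], [5.0, 5.0, 10.0]])
        model = np.array([[12.0, 18.0, 44.0], [4.0, 6.0, 9.0]])
        rep = evaluate(model, data, model, data)
        pct = 100 * (model - data) / data
        assert rep.live.mean_pct_error == pytest.approx(pct.mean())
        assert rep.live.pct_error_eoe == pytest.approx(pct[:, -1].mean())
        assert rep.live.mean_error == pytest.approx((model - data).mean())
        assert rep.live.error_eoe == pytest.approx((model - data)[:, -1].mean())
        rss_oracle = (((model - data) / 100.0) ** 2).sum(axis=1).mean()
        assert rep.live.rss == pytest.approx(rss_oracle)

    def test_sign_agreement_on_constant_sign_data(self):
        d = np.array([[10.0, 20.0]])
        m = 0.9 * d
        rep = evaluate(m, d, m, d)
        assert rep.live.mean_pct_error < 0 and rep.live.mean_error < 0


@pytest.fixture(scope="module")
def small_fit(bt_profile):
    design = CohortDesign(glucose_levels_mm=(0.5, 5.0), tiers_pct=(24.0, 52.0),
                          replicates=1, k_bys_lognorm_sigma=0.0)
    cohort = generate_cohort(bt_profile, design, seed=13)
    cfg = CalibrationConfig(n_starts=2, seed=0)
    mixed = fit_mixed(cohort, 2, cfg)
    law = _fit_law_from_mixed(mixed, cohort, "surface", True, cfg)
    return cohort, mixed, law, cfg


class TestPredictAndUncertainty:

    def test_training_uncertainty_tracks_noise_level(self, small_fit, bt_profile):
        cohort, mixed, law, cfg = small_fit
        u_live, u_dead = training_uncertainty(mixed, cohort, cfg)
        expected = bt_profile.noise_live_pct * np.sqrt(2 / np.pi)
        assert u_live == pytest.approx(expected, rel=1.0)
        assert 0 < u_live < 2 * bt_profile.noise_live_pct
        assert u_dead > u_live  # dead channel is noisier

    def test_zero_uncertainty_band_collapses(self, small_fit):
        cohort, mixed, law, cfg = small_fit
        zero_ci = FitResult(
            estimates=mixed.shared.estimates,
            ci95={k: 0.0 for k in mixed.shared.ci95},
            rss=0.0, residuals=np.zeros(0), n_obs=0,
            scenario="mixed", variant=2,
        )
        law0 = BystanderLaw(form=law.form, k_bys0=law.k_bys0, alpha=law.alpha,
                            ci95={k: 0.0 for k in law.param_names})
        band = predict(cohort[0], zero_ci, law0, (0.0, 0.0), n_draws=150,
                       seed=5, config=cfg)
        assert np.allclose(band.live_lo, band.live_hi)
        assert np.allclose(band.live_lo, band.live_mean)

    def test_band_deterministic_given_seed(self, small_fit):
        cohort, mixed, law, cfg = small_fit
        a = predict(cohort[0], mixed.shared, law, (5.0, 15.0), n_draws=150,
                    seed=9, config=cfg)
        b = predict(cohort[0], mixed.shared, law, (5.0, 15.0), n_draws=150,
                    seed=9, config=cfg)
        assert np.array_equal(a.live_lo, b.live_lo)

    def test_wider_parameter_ci_widens_band(self, small_fit):
        cohort, mixed, law, cfg = small_fit
        est = mixed.shared.estimates
        narrow = FitResult(estimates=est, ci95={"k_p": 0.005, "k_d": 0.0, "v": 0.0},
                           rss=0.0, residuals=np.zeros(0), n_obs=0,
                           scenario="mixed", variant=2)
        wide = FitResult(estimates=est, ci95={"k_p": 0.01, "k_d": 0.0, "v": 0.0},
                         rss=0.0, residuals=np.zeros(0), n_obs=0,
                         scenario="mixed", variant=2)
        law0 = BystanderLaw(form=law.form, k_bys0=law.k_bys0, alpha=law.alpha,
                            ci95={k: 0.0 for k in law.param_names})
        b1 = predict(cohort[0], narrow, law0, (0.0, 0.0), n_draws=400, seed=3, config=cfg)
        b2 = predict(cohort[0], wide, law0, (0.0, 0.0), n_draws=400, seed=3, config=cfg)
        w1 = b1.live_hi[-1] - b1.live_lo[-1]
        w2 = b2.live_hi[-1] - b2.live_lo[-1]
        assert w2 > w1

    def test_too_few_draws_refused(self, small_fit):
        cohort, mixed, law, cfg = small_fit
        with pytest.raises(ValueError):
            predict(cohort[0], mixed.shared, law, (0.0, 0.0), n_draws=50, config=cfg)


class TestRunRounds:
    def test_small_cohort_end_to_end(self, bt_profile):
        design = CohortDesign(glucose_levels_mm=(0.2, 1.0, 5.0),
                              tiers_pct=(24.0, 52.0), replicates=1,
                              k_bys_lognorm_sigma=0.0)
        cohort = generate_cohort(bt_profile, design, seed=17)
        cfg = CalibrationConfig(n_starts=2, seed=0)
        summary = run_rounds(cohort, n_rounds=2, seed=12, law_form="surface",
                             n_draws=150, config=cfg)
        assert summary.loc["effective_rounds", "mean"] == 2
        acc = summary.loc["val_accuracy_live", "mean"]
        assert 0.0 <= acc <= 1.0
        # live channel is predicted better than the noisier dead channel
        assert acc >= summary.loc["val_accuracy_dead", "mean"] - 0.25

    def test_requires_multiple_rounds(self, bt_cohort_noisy, fast_config):
        with pytest.raises(ValueError):
            run_rounds(bt_cohort_noisy, n_rounds=1, config=fast_config)
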