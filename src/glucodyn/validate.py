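"""Train/validate evaluation of the calibrated model.

One round: randomly split the cohort 75/25, run the mixed calibration on the
training wells, fit the bystander law to the training k_bys estimates, then
for each validation well look up k_bys from its initial conditions, propagate
parameter and initial-condition uncertainty through the forward model by
Monte Carlo, and score the measured series against the 95% prediction band.
Repeating the round gives across-round means with normal-approximation CIs.

Error metrics per series (live and dead, signed throughout):

* rss            -- summed squared error on fractional confluence (0-1),
                    averaged per well, reported as the cohort mean;
* mean % error   -- mean of 100 (model - data)/data over all time points
                    (zero-data points excluded and counted);
* % error EoE    -- the same at the final time point only;
* mean error     -- mean of (model - data), confluence %;
* error EoE      -- the same at the final time point;
* accuracy       -- fraction of measured points inside the 95% band
                    (validation only);
* uncertainty    -- mean |fit - data| relative to the data mean, % (training
                    only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .bystander import BystanderLaw, fit_curve, fit_surface
from .calibrate import (
    ANCHOR_INDEX,
    CalibrationConfig,
    CalibrationError,
    FitResult,
    MixedFit,
    _simulate_stacked,
    estimate_initial_state,
    fit_mixed,
)

if TYPE_CHECKING:
    from .synth import Cohort, TimeCoursePair

__all__ = [
    "SplitPlan",
    "PredictionBand",
    "EvaluationReport",
    "split_cohort",
    "training_uncertainty",
    "predict",
    "accuracy",
    "evaluate",
    "run_rounds",
]


@dataclass(frozen=True)
class SplitPlan:
    round_id: int
    train_ids: tuple
    validation_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        train, val = set(self.train_ids), set(self.validation_ids)
        if train & val:
            raise ValueError("train and validation sets overlap")


def split_cohort(cohort: "Cohort", fraction: float = 0.75, seed: int = 0,
                 round_id: int = 0) -> SplitPlan:
    """Uniform random partition of well indices without replacement."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(cohort)
    if n < 4:
        raise ValueError("cohort must have >= 4 wells to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(
        round_id=round_id,
        train_ids=tuple(int(i) for i in np.sort(perm[:n_train])),
        validation_ids=tuple(int(i) for i in np.sort(perm[n_train:])),
        seed=seed,
    )


def _predicted_series(pair, estimates, k_bys, config, n0=None, d0=None):
    """Noise-free model series for one well at given parameter values."""
    init = estimate_initial_state(pair)
    n0 = init.n0 if n0 is None else n0
    d0 = init.d0 if d0 is None else d0
    live, dead = _simulate_stacked(
        pair.times, np.array([n0]), np.array([d0]), np.array([pair.g0_mm]),
        estimates["k_p"], estimates.get("k_d", 0.0), k_bys, estimates["v"],
        config.theta, config.g_star, config.g_min, config.cells_per_pct,
        config.ode_rtol, config.ode_atol, anchor=ANCHOR_INDEX,
    )
    if live is None:
        raise CalibrationError(f"forward simulation failed for well {pair.well_id}")
    return live[0], dead[0]


def training_uncertainty(mixed: MixedFit, cohort: "Cohort",
                         config: CalibrationConfig | None = None):
    """Mean absolute fit-data deviation as % of the data mean, live and dead.

    Estimates the measurement uncertainty of the confluence series from the
    training-set residuals of the best fit; used as the initial-condition
    uncertainty when forming predictions.
    """
    config = config or CalibrationConfig()
    pairs = list(cohort)
    if not pairs:
        raise ValueError("empty training set")
    abs_live, abs_dead, all_live, all_dead = [], [], [], []
    kbys = {f.well_id: f.estimates["k_bys"] for f in mixed.locals_}
    for p in pairs:
        ml, md = _predicted_series(p, mixed.shared.estimates,
                                   kbys.get(p.well_id, 0.0), config)
        abs_live.append(np.abs(ml - p.live))
        abs_dead.append(np.abs(md - p.dead))
        all_live.append(p.live)
        all_dead.append(p.dead)
    live_mean = float(np.concatenate(all_live).mean())
    dead_mean = float(np.concatenate(all_dead).mean())
    u_live = 100.0 * float(np.concatenate(abs_live).mean()) / live_mean
    u_dead = 100.0 * float(np.concatenate(abs_dead).mean()) / dead_mean
    return u_live, u_dead


@dataclass
class PredictionBand:
    """Pointwise Monte-Carlo mean and 95% bounds for one well's prediction."""

    times: np.ndarray
    live_mean: np.ndarray
    live_lo: np.ndarray
    live_hi: np.ndarray
    dead_mean: np.ndarray
    dead_lo: np.ndarray
    dead_hi: np.ndarray
    n_draws: int

    def __post_init__(self) -> None:
        for lo, mean, hi in ((self.live_lo, self.live_mean, self.live_hi),
                             (self.dead_lo, self.dead_mean, self.dead_hi)):
            if np.any(lo > mean + 1e-9) or np.any(mean > hi + 1e-9):
                raise ValueError("band bounds must satisfy lo <= mean <= hi")
            if np.any(lo < -1e-9):
                raise ValueError("band bounds must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "live_mean": self.live_mean, "live_lo": self.live_lo, "live_hi": self.live_hi,
                "dead_mean": self.dead_mean, "dead_lo": self.dead_lo, "dead_hi": self.dead_hi,
            }
        )


def _truncnorm(rng, mean, half_ci, size):
    """Normal draws with sd = half_ci/1.96, truncated at 0 by resampling-free
    clipping (half-widths here are small relative to the means)."""
    sd = np.asarray(half_ci, dtype=float) / 1.96
    return np.maximum(rng.normal(mean, sd, size=size), 0.0)


def predict(
    pair: "TimeCoursePair",
    globals_fit: FitResult,
    law: BystanderLaw,
    uncertainty_pct: tuple = (0.0, 0.0),
    n_draws: int = 1000,
    seed: int = 0,
    config: CalibrationConfig | None = None,
    law_n0_in_cells: bool = True,
) -> PredictionBand:
    """Monte-Carlo 95% prediction band for one validation well.

    Draws (k_p, k_d, v) from independent truncated normals defined by the
    global estimates and their CI half-widths, the initial live/dead
    abundances from the training-set uncertainty, and k_bys by drawing the
    law's parameters from their CIs and evaluating at the well's initial
    conditions; each draw is simulated forward and the band is the pointwise
    2.5/97.5 percentile envelope with the pointwise mean.
    """
    if n_draws < 100:
        raise ValueError("n_draws < 100 gives an unstable band")
    config = config or CalibrationConfig()
    rng = np.random.default_rng(seed)
    est = globals_fit.estimates
    ci = globals_fit.ci95
    init = estimate_initial_state(pair)
    u_live, u_dead = uncertainty_pct

    kp = _truncnorm(rng, est["k_p"], ci.get("k_p", 0.0), n_draws)
    kd = _truncnorm(rng, est.get("k_d", 0.0), ci.get("k_d", 0.0), n_draws)
    v = _truncnorm(rng, est["v"], ci.get("v", 0.0), n_draws)
    n0 = _truncnorm(rng, init.n0, 1.96 * init.n0 * u_live / 100.0, n_draws)
    d0 = _truncnorm(rng, init.d0, 1.96 * init.d0 * u_dead / 100.0, n_draws)

    law_kw = {k: _truncnorm(rng, getattr(law, k), law.ci95.get(k, 0.0), n_draws)
              for k in law.param_names}
    n0_law = n0 * (config.cells_per_pct if law_n0_in_cells else 1.0)
    if law.form == "surface":
        kbys = law_kw["k_bys0"] * n0_law * np.exp(-law_kw["alpha"] * pair.g0_mm)
    else:
        kbys = law_kw["k_bys0"] * np.exp(-law_kw["alpha"] * pair.g0_mm) + law_kw["beta"]

    g0 = np.full(n_draws, pair.g0_mm)
    lives, deads = [], []
    # simulate draws in blocks as one stacked system
    block = 250
    for i in range(0, n_draws, block):
        sl = slice(i, min(i + block, n_draws))
        # rates differ per draw; stack wells with identical shared rates is
        # not possible, so loop draws with a per-draw 1-well solve unless the
        # rates are constant.  Blocked stacking applies when only k_bys and
        # initial states vary; with rate draws we integrate draw-by-draw on
        # the same grid, which stays affordable at the default draw count.
        for j in range(sl.start, sl.stop):
            ml, md = _simulate_stacked(
                pair.times, n0[j : j + 1], d0[j : j + 1], g0[j : j + 1],
                kp[j], kd[j], kbys[j : j + 1], v[j],
                config.theta, config.g_star, config.g_min, config.cells_per_pct,
                1e-6, 1e-8, anchor=ANCHOR_INDEX,
            )
            if ml is None:
                continue
            lives.append(ml[0])
            deads.append(md[0])
    if not lives:
        raise CalibrationError(f"all prediction draws failed for well {pair.well_id}")
    L = np.vstack(lives)
    D = np.vstack(deads)
    return PredictionBand(
        times=pair.times,
        live_mean=L.mean(axis=0),
        live_lo=np.percentile(L, 2.5, axis=0),
        live_hi=np.percentile(L, 97.5, axis=0),
        dead_mean=D.mean(axis=0),
        dead_lo=np.percentile(D, 2.5, axis=0),
        dead_hi=np.percentile(D, 97.5, axis=0),
        n_draws=len(lives),
    )


def accuracy(band: PredictionBand, pair: "TimeCoursePair"):
    """Fraction of measured points inside the band, (live, dead)."""
    if len(band.times) != len(pair.times) or not np.allclose(band.times, pair.times):
        raise ValueError("band grid does not match the measured grid")
    live_in = (pair.live >= band.live_lo) & (pair.live <= band.live_hi)
    dead_in = (pair.dead >= band.dead_lo) & (pair.dead <= band.dead_hi)
    return float(live_in.mean()), float(dead_in.mean())


@dataclass
class SeriesMetrics:
    rss: float
    mean_pct_error: float
    pct_error_eoe: float
    mean_error: float
    error_eoe: float
    n_zero_excluded: int = 0

    def as_dict(self, prefix=""):
        return {
            f"{prefix}rss": self.rss,
            f"{prefix}mean_pct_error": self.mean_pct_error,
            f"{prefix}pct_error_eoe": self.pct_error_eoe,
            f"{prefix}mean_error": self.mean_error,
            f"{prefix}error_eoe": self.error_eoe,
        }


@dataclass
class EvaluationReport:
    live: SeriesMetrics
    dead: SeriesMetrics
    accuracy_live: float | None = None
    accuracy_dead: float | None = None
    uncertainty_live: float | None = None
    uncertainty_dead: float | None = None

    def __post_init__(self) -> None:
        for a in (self.accuracy_live, self.accuracy_dead):
            if a is not None and not 0.0 <= a <= 1.0:
                raise ValueError("accuracy must be in [0, 1]")


def _series_metrics(model: np.ndarray, data: np.ndarray) -> SeriesMetrics:
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model and data series must be aligned")
    err = model - data
    nonzero = data != 0
    pct = 100.0 * err[nonzero] / data[nonzero]
    eoe_pct = (
        float(100.0 * err[..., -1].mean() / data[..., -1].mean())
        if np.all(data[..., -1] != 0)
        else float("nan")
    )
    if data.ndim == 1:
        eoe_pct = float(100.0 * err[-1] / data[-1]) if data[-1] != 0 else float("nan")
        rss = float(((err / 100.0) ** 2).sum())
        eoe = float(err[-1])
    else:
        # rows are wells: per-well RSS on fractional confluence, cohort mean
        rss = float(((err / 100.0) ** 2).sum(axis=1).mean())
        eoe = float(err[..., -1].mean())
        nz_end = data[..., -1] != 0
        eoe_pct = (
            float((100.0 * err[..., -1][nz_end] / data[..., -1][nz_end]).mean())
            if nz_end.any()
            else float("nan")
        )
    return SeriesMetrics(
        rss=rss,
        mean_pct_error=float(pct.mean()) if pct.size else float("nan"),
        pct_error_eoe=eoe_pct,
        mean_error=float(err.mean()),
        error_eoe=eoe,
        n_zero_excluded=int((~nonzero).sum()),
    )


def evaluate(model_live, data_live, model_dead, data_dead) -> EvaluationReport:
    """Signed error metrics of model series against measured series.

    Inputs may be single series (1-d) or well-by-time matrices (2-d); zero
    data values are excluded from percent-error means and counted in
    ``n_zero_excluded``.
    """
    return EvaluationReport(
        live=_series_metrics(model_live, data_live),
        dead=_series_metrics(model_dead, data_dead),
    )


def _fit_law_from_mixed(mixed: MixedFit, cohort, form: str, n0_in_cells: bool,
                        config: CalibrationConfig):
    pairs = {p.well_id: p for p in cohort}
    n0, g0, k, ci = [], [], [], []
    for f in mixed.locals_:
        p = pairs[f.well_id]
        n0.append(p.n0_pct * (config.cells_per_pct if n0_in_cells else 1.0))
        g0.append(p.g0_mm)
        k.append(f.estimates["k_bys"])
        half = f.ci95.get("k_bys", 0.0)
        ci.append(half if np.isfinite(half) else 0.0)
    if form == "surface":
        return fit_surface(n0, g0, k, ci)
    return fit_curve(g0, k, ci)


@dataclass
class RoundResult:
    plan: SplitPlan
    report_train: EvaluationReport
    report_validation: EvaluationReport
    law: BystanderLaw


def run_rounds(
    cohort: "Cohort",
    n_rounds: int = 50,
    seed: int = 0,
    fraction: float = 0.75,
    law_form: str = "surface",
    law_n0_in_cells: bool = True,
    n_draws: int = 1000,
    config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Repeated train/validate rounds; returns across-round summary statistics.

    Each round: split -> mixed calibration on the training wells -> bystander
    law fit on the training k_bys estimates -> Monte-Carlo prediction of each
    validation well -> scoring.  The summary holds the across-round mean and
    a normal-approximation 95% CI for every metric, plus the effective round
    count (rounds whose calibration failed are skipped and logged).
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    config = config or CalibrationConfig()
    master = np.random.default_rng(seed)
    rows = []
    for r in range(n_rounds):
        round_seed = int(master.integers(2**31 - 1))
        plan = split_cohort(cohort, fraction=fraction, seed=round_seed, round_id=r)
        train = cohort.subset(plan.train_ids)
        val = cohort.subset(plan.validation_ids)
        try:
            mixed = fit_mixed(train, 2, replace(config, seed=round_seed))
            law = _fit_law_from_mixed(mixed, train, law_form, law_n0_in_cells, config)
            u = training_uncertainty(mixed, train, config)
        except (CalibrationError, ValueError, RuntimeError):
            continue
        # training metrics
        kbys = {f.well_id: f.estimates["k_bys"] for f in mixed.locals_}
        ml = np.vstack([_predicted_series(p, mixed.shared.estimates, kbys[p.well_id], config)[0] for p in train])
        md = np.vstack([_predicted_series(p, mixed.shared.estimates, kbys[p.well_id], config)[1] for p in train])
        rep_t = evaluate(ml, np.vstack([p.live for p in train]),
                         md, np.vstack([p.dead for p in train]))
        rep_t.uncertainty_live, rep_t.uncertainty_dead = u
        # validation predictions
        acc_l, acc_d, pl, pd_, dl, dd = [], [], [], [], [], []
        for j, p in enumerate(val):
            band = predict(p, mixed.shared, law, u, n_draws=n_draws,
                           seed=round_seed + 7919 * (j + 1), config=config,
                           law_n0_in_cells=law_n0_in_cells)
            a_l, a_d = accuracy(band, p)
            acc_l.append(a_l)
            acc_d.append(a_d)
            pl.append(band.live_mean)
            pd_.append(band.dead_mean)
            dl.append(p.live)
            dd.append(p.dead)
        rep_v = evaluate(np.vstack(pl), np.vstack(dl), np.vstack(pd_), np.vstack(dd))
        rep_v.accuracy_live = float(np.mean(acc_l))
        rep_v.accuracy_dead = float(np.mean(acc_d))
        row = {"round": r}
        row.update(rep_t.live.as_dict("train_live_"))
        row.update(rep_t.dead.as_dict("train_dead_"))
        row.update(rep_v.live.as_dict("val_live_"))
        row.update(rep_v.dead.as_dict("val_dead_"))
        row["train_uncertainty_live"] = u[0]
        row["train_uncertainty_dead"] = u[1]
        row["val_accuracy_live"] = rep_v.accuracy_live
        row["val_accuracy_dead"] = rep_v.accuracy_dead
        rows.append(row)
    if not rows:
        raise CalibrationError("every round failed")
    per_round = pd.DataFrame(rows).set_index("round")
    mean = per_round.mean()
    half = 1.96 * per_round.std(ddof=1) / np.sqrt(len(per_round))
    summary = pd.DataFrame({"mean": mean, "ci95_half": half})
    summary.loc["effective_rounds"] = [len(per_round), 0.0]
    summary.attrs["per_round"] = per_round
    return summary
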