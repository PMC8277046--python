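"""Nonlinear least-squares calibration of the growth model to time courses.

Three scenarios mirror how the kinetic rates may vary across a plate:

* local  -- every well gets its own parameter set (lowest error, most prone
  to overfitting);
* global -- one shared parameter set for the whole cohort;
* mixed  -- k_p, k_d, v shared across the cohort, the bystander rate k_bys
  fitted per well (the configuration selected by AICc on this system).

All fits minimize a least-squares objective over the concatenated live and
dead confluence residuals, with glucose latent and initialized at the known
G0, and the initial live/dead abundances taken as the mean of the first
three observed time points.  Optimization is bounded trust-region-reflective
least squares with multistart (log-uniform initial guesses); 95% confidence
intervals are linearized Gauss-Newton intervals from the residuals and
Jacobian at the optimum.

Because confluence noise is multiplicative (a fixed percentage of signal),
the default objective is generalized least squares: each residual is scaled
by an estimated per-point noise sd built from a moving-average smooth of its
own series, with the live/dead noise levels estimated from the smooth
residuals.  Ordinary unweighted least squares (``weighting="none"``) remains
available; under the strongly heteroscedastic dead-cell noise it is markedly
less efficient and the large noisy dead values drown the live channel's
information about the consumption rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

if TYPE_CHECKING:  # avoid an import cycle with synth (which needs BystanderLaw)
    from .synth import Cohort, TimeCoursePair

__all__ = [
    "CalibrationConfig",
    "CalibrationError",
    "NonIdentifiableError",
    "InitialStateEstimate",
    "FitResult",
    "MixedFit",
    "estimate_initial_state",
    "confidence_intervals",
    "fit_local",
    "fit_local_all",
    "fit_global",
    "fit_mixed",
]

#: Free kinetic parameters per model variant (theta, G*, G_min stay fixed).
VARIANT_FREE = {
    1: ("k_p", "k_d", "v"),
    2: ("k_p", "k_d", "k_bys", "v"),
    3: ("k_p", "k_bys", "v"),
}

#: Shared parameters of the mixed scenario (k_bys, when present, is local).
MIXED_SHARED = {
    1: ("k_p", "k_d", "v"),
    2: ("k_p", "k_d", "v"),
    3: ("k_p", "v"),
}

_DEFAULT_BOUNDS = {
    "k_p": (0.0, 2.0),
    "k_d": (0.0, 2.0),
    "k_bys": (0.0, 2.0),
    "v": (0.0, 1e-3),
}
_GUESS_RANGES = {
    "k_p": (1e-3, 2.0),
    "k_d": (1e-3, 2.0),
    "k_bys": (1e-3, 2.0),
    "v": (1e-7, 1e-3),
}
_X_SCALE = {"k_p": 0.1, "k_d": 0.1, "k_bys": 0.1, "v": 1e-5}

#: The three-point initial-abundance average estimates the state at the
#: middle frame of the averaging window, so simulated fits are anchored at
#: grid index 1 and the first frame is recovered by backward integration.
ANCHOR_INDEX = 1


class CalibrationError(RuntimeError):
    """All multistart runs failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NonIdentifiableError(np.linalg.LinAlgError):
    """Rank-deficient Jacobian; names the degenerate parameter directions."""

    def __init__(self, directions):
        self.directions = list(directions)
        super().__init__(
            "Jacobian is rank deficient; non-identifiable directions involve: "
            + ", ".join(self.directions)
        )


@dataclass(frozen=True)
class CalibrationConfig:
    """Optimizer and multistart settings.

    ``n_starts`` log-uniform initial guesses are drawn within the guess
    ranges; the lowest-RSS solution wins.  ODE tolerances apply to the
    forward simulations inside the objective.
    """

    n_starts: int = 10
    seed: int = 0
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    guess_ranges: dict = field(default_factory=lambda: dict(_GUESS_RANGES))
    ftol: float = 1e-10
    xtol: float = 1e-8
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    # residual weighting: "gls" scales residuals by estimated per-point noise
    # sd (multiplicative-noise model); "none" is ordinary least squares
    weighting: str = "gls"
    weight_floor_pct: float = 0.5
    weight_smooth_window: int = 7
    # measurement-error treatment of initial conditions: each well's anchor
    # (N0, D0) becomes a bounded parameter with a prior residual tying it to
    # the three-frame mean at that mean's noise sd.  Without this, anchor
    # noise leaves a per-well misfit that only per-well rate parameters can
    # absorb, which biases both recovery and model comparison.
    fit_initial_conditions: bool = True
    # fixed constants (assigned, never fitted)
    theta: float = 100.0
    g_star: float = 1.0
    g_min: float = 0.1
    cells_per_pct: float = 800.0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.weighting not in ("gls", "none"):
            raise ValueError(f"weighting must be 'gls' or 'none', got {self.weighting!r}")


class InitialStateEstimate(NamedTuple):
    n0: float
    d0: float
    n0_se: float
    d0_se: float


def estimate_initial_state(pair: "TimeCoursePair") -> InitialStateEstimate:
    """Initial live/dead abundances as the mean of the first three time points.

    Averaging damps measurement noise in the single day-0 frame; the standard
    errors of those three-point means quantify the residual uncertainty.
    """
    if len(pair) < 3:
        raise ValueError(f"well {pair.well_id}: need >= 3 time points")
    live3 = pair.live[:3]
    dead3 = pair.dead[:3]
    return InitialStateEstimate(
        n0=float(live3.mean()),
        d0=float(dead3.mean()),
        n0_se=float(live3.std(ddof=1) / np.sqrt(3)),
        d0_se=float(dead3.std(ddof=1) / np.sqrt(3)),
    )


@dataclass
class FitResult:
    """Point estimates, linearized 95% CIs, and fit provenance."""

    estimates: dict
    ci95: dict
    rss: float
    residuals: np.ndarray
    n_obs: int
    scenario: str
    variant: int
    well_id: str | None = None
    n_free: int = 0
    jacobian: np.ndarray | None = None
    #: minimized objective; equals ``rss`` under weighting="none", otherwise
    #: the weighted residual sum of squares (the model-comparison quantity)
    objective: float | None = None

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if self.n_obs != len(self.residuals):
            raise ValueError("n_obs must equal the residual count")
        if any(h < 0 for h in self.ci95.values()):
            raise ValueError("CI half-widths must be >= 0")
        if self.objective is None:
            self.objective = self.rss

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": k,
                "estimate": v,
                "ci_low": v - self.ci95.get(k, np.nan),
                "ci_high": v + self.ci95.get(k, np.nan),
                "scenario": self.scenario,
                "variant": self.variant,
                "well_id": self.well_id if self.well_id is not None else "global",
            }
            for k, v in self.estimates.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class MixedFit:
    """Result of the mixed scenario: shared rates plus one k_bys per well."""

    shared: FitResult
    locals_: list
    rss: float
    n_obs: int
    variant: int
    objective: float | None = None

    def __post_init__(self) -> None:
        if self.objective is None:
            self.objective = self.rss

    @property
    def n_free(self) -> int:
        return self.shared.n_free

    def k_bys_table(self) -> pd.DataFrame:
        rows = []
        for f in self.locals_:
            rows.append(
                {
                    "well_id": f.well_id,
                    "k_bys": f.estimates["k_bys"],
                    "ci95": f.ci95.get("k_bys", np.nan),
                }
            )
        return pd.DataFrame(rows)


def confidence_intervals(residuals, jacobian, level: float = 0.95):
    """Linearized (Gauss-Newton) CI half-widths from a least-squares solution.

    half_k = t(1 - a/2, n - p) * sqrt(s^2 [(J^T J)^-1]_kk),  s^2 = RSS/(n-p).

    Raises :class:`NonIdentifiableError` when the Jacobian is rank deficient,
    naming the parameters that dominate the degenerate directions.
    """
    r = np.asarray(residuals, dtype=float)
    J = jacobian.toarray() if sparse.issparse(jacobian) else np.asarray(jacobian, dtype=float)
    n, p = J.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if s.size == 0 or s[-1] <= tol:
        bad = []
        for row in Vt[s <= tol]:
            bad.append(f"p{int(np.argmax(np.abs(row)))}")
        raise NonIdentifiableError(bad or ["all"])
    rss = float(r @ r)
    s2 = rss / (n - p)
    # diag of (J^T J)^-1 via the SVD: V diag(1/s^2) V^T
    diag_inv = ((Vt.T / s) ** 2).sum(axis=1)
    half = t_dist.ppf(0.5 + level / 2.0, n - p) * np.sqrt(s2 * diag_inv)
    return half


# ---------------------------------------------------------------------------
# stacked forward simulation of many wells


def _stack_pairs(pairs):
    grids = [p.times for p in pairs]
    same = all(len(g) == len(grids[0]) and np.allclose(g, grids[0]) for g in grids)
    if not same:
        raise ValueError("all wells must share one time grid for joint fitting")
    init = [estimate_initial_state(p) for p in pairs]
    n0 = np.array([e.n0 for e in init])
    d0 = np.array([e.d0 for e in init])
    g0 = np.array([p.g0_mm for p in pairs])
    live = np.vstack([p.live for p in pairs])
    dead = np.vstack([p.dead for p in pairs])
    return grids[0], n0, d0, g0, live, dead


def _simulate_stacked(grid, n0, d0, g0, kp, kd, kbys, v, theta, g_star, g_min,
                      cells_per_pct, rtol, atol, anchor: int = 0):
    """Simulate P wells as one 3P-dimensional ODE system; returns (live, dead)
    arrays of shape (P, T).  ``kbys`` may be a scalar or a per-well vector.

    ``anchor`` is the grid index at which the initial state applies.  The
    three-point initial-abundance average approximates the trajectory at the
    middle of the averaging window, so fits anchor there (anchor=1) and the
    earlier grid points are recovered by integrating backward in time.
    """
    P = len(n0)
    kbys = np.broadcast_to(np.asarray(kbys, dtype=float), (P,))
    g_anchor = np.asarray(g0, dtype=float)
    if anchor > 0:
        # G0 is known at t = 0; advance it to the anchor time with the
        # consumption ODE (live abundance held at its anchor value -- it
        # varies by well under 1% over the two frames this spans)
        def gdot(g):
            g = np.maximum(g, 0.0)
            return -v * cells_per_pct * n0 * g / (g + g_star)

        nstep = 4
        h = grid[anchor] / nstep
        g_anchor = g_anchor.copy()
        for _ in range(nstep):
            k1 = gdot(g_anchor)
            k2 = gdot(g_anchor + 0.5 * h * k1)
            k3 = gdot(g_anchor + 0.5 * h * k2)
            k4 = gdot(g_anchor + h * k3)
            g_anchor = np.maximum(g_anchor + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    def fun(t, y):
        n = y[:P]
        d = y[P : 2 * P]
        g = np.maximum(y[2 * P :], 0.0)
        sd = (1.0 - g / (g + g_min)) * np.tanh(t)
        sp = 1.0 - sd
        logistic = kp * n * (1.0 - n / theta) * sp
        starv = kd * n * sd
        den = n + d
        frac = np.divide(d, den, out=np.zeros(P), where=den > 0)
        bys = kbys * n * frac
        return np.concatenate(
            [logistic - starv - bys, starv + bys, -v * cells_per_pct * n * g / (g + g_star)]
        )

    t_anchor = grid[anchor]
    y0 = np.concatenate([n0, d0, g_anchor])
    if anchor == 1 and len(grid) >= 3:
        # the three-frame average equals y(t1) + h^2/3 * y''(t1) + O(h^4);
        # remove the curvature term so the anchor is the trajectory value,
        # estimating y'' by differencing f along the flow
        h = grid[1] - grid[0]
        if np.allclose(np.diff(grid[:3]), h):
            eps = 1e-6
            f1 = fun(t_anchor, y0)
            f2 = fun(t_anchor + eps, y0 + eps * f1)
            ypp = (f2 - f1) / eps
            corr = (h * h / 3.0) * ypp
            corr[2 * P :] = 0.0  # glucose anchor comes from the G0 propagation
            y0 = y0 - corr
            y0[: 2 * P] = np.maximum(y0[: 2 * P], 0.0)
    sol = solve_ivp(fun, (t_anchor, grid[-1]), y0, method="RK45",
                    t_eval=grid[anchor:], rtol=rtol, atol=atol)
    if not sol.success:
        return None, None
    y = sol.y
    if anchor > 0:
        back = solve_ivp(fun, (t_anchor, grid[0]), y0, method="RK45",
                         t_eval=grid[:anchor][::-1], rtol=rtol, atol=atol)
        if not back.success:
            return None, None
        y = np.hstack([back.y[:, ::-1], sol.y])
    live = y[:P]
    dead = y[P : 2 * P]
    return live, dead


# ---------------------------------------------------------------------------
# generic multistart driver


def _base(name: str) -> str:
    return name.split("[")[0]


def _bound(name, config):
    base = _base(name)
    if base in config.bounds:
        return config.bounds[base]
    if base == "n0":
        return (1e-3, 2.0 * config.theta)
    if base == "d0":
        return (0.0, config.theta)
    raise KeyError(name)


def _xscale(name):
    base = _base(name)
    if base in _X_SCALE:
        return _X_SCALE[base]
    return {"n0": 10.0, "d0": 1.0}[base]


def _multistart(residual_fn, names, config: CalibrationConfig, jac_sparsity=None,
                fixed_starts=None):
    """Run ``n_starts`` bounded TRF solves and return the lowest-cost one.

    Kinetic parameters start log-uniform within their guess ranges;
    ``fixed_starts`` maps parameter names to deterministic start values (used
    for initial-condition nuisance parameters, which always start at their
    measured anchors).
    """
    rng = np.random.default_rng(config.seed)
    fixed_starts = fixed_starts or {}
    kin = [n for n in names if _base(n) in config.guess_ranges]
    lo = np.array([config.guess_ranges[_base(n)][0] for n in kin])
    hi = np.array([config.guess_ranges[_base(n)][1] for n in kin])
    u = rng.uniform(size=(config.n_starts, len(kin)))
    kin_starts = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    starts = np.empty((config.n_starts, len(names)))
    j = 0
    for c, n in enumerate(names):
        if n in fixed_starts:
            starts[:, c] = fixed_starts[n]
        else:
            starts[:, c] = kin_starts[:, j]
            j += 1
    lb = np.array([_bound(n, config)[0] for n in names])
    ub = np.array([_bound(n, config)[1] for n in names])
    x_scale = np.array([_xscale(n) for n in names])
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = least_squares(
                residual_fn,
                np.clip(x0, lb, ub),
                bounds=(lb, ub),
                method="trf",
                x_scale=x_scale,
                ftol=config.ftol,
                xtol=config.xtol,
                jac_sparsity=jac_sparsity,
            )
        except Exception as exc:  # keep going; other starts may succeed
            diagnostics.append(f"start failed: {exc}")
            continue
        diagnostics.append(f"cost={res.cost:.6g} status={res.status}")
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise CalibrationError("no multistart run converged", diagnostics)
    return best


# ---------------------------------------------------------------------------
# residual weighting


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = np.pad(y, ((0, 0), (window // 2, window // 2)), mode="edge")
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, pad)


def _gls_weights(live, dead, config: CalibrationConfig):
    """Per-point inverse noise-sd weights under a multiplicative-noise model.

    The signal is approximated by a moving-average smooth of each series; the
    per-channel relative noise level is estimated from the smooth residuals,
    and sigma_ij = level * max(smooth_ij, floor).  Weights depend on the data
    only (not on model parameters), keeping the objective a fixed least
    squares problem.
    """
    floor = config.weight_floor_pct
    out = []
    for y in (live, dead):
        yhat = _moving_average(y, config.weight_smooth_window)
        denom = np.maximum(yhat, floor)
        level = float(np.sqrt(np.mean(((y - yhat) / denom) ** 2)))
        level = max(level, 1e-3)
        out.append(1.0 / (level * denom))
    return out


# ---------------------------------------------------------------------------
# public fitting entry points


def _fit_pairs(pairs, variant, config, free_shared, per_pair_kbys, weights=None):
    """Shared machinery behind the local/global/mixed scenarios.

    ``weights`` optionally supplies precomputed (w_live, w_dead) arrays of
    shape (P, T); model selection passes one cohort-wide set so that the
    minimized objectives of different candidates are commensurable.
    """
    grid, anchor_n0, anchor_d0, g0, live, dead = _stack_pairs(pairs)
    P = len(pairs)
    T = len(grid)
    ns = len(free_shared)
    names = list(free_shared) + (
        [f"k_bys[{p.well_id}]" for p in pairs] if per_pair_kbys else []
    )
    nk = len(names)
    fit_ics = config.fit_initial_conditions
    fixed_starts = {}
    if fit_ics:
        for p, a_n, a_d in zip(pairs, anchor_n0, anchor_d0):
            names.append(f"n0[{p.well_id}]")
            fixed_starts[f"n0[{p.well_id}]"] = a_n
        for p, a_d in zip(pairs, anchor_d0):
            names.append(f"d0[{p.well_id}]")
            fixed_starts[f"d0[{p.well_id}]"] = a_d
    m = 2 * P * T
    m_total = m + (2 * P if fit_ics else 0)
    big = np.full(m_total, 1e6)
    if weights is not None:
        w_live, w_dead = weights
    elif config.weighting == "gls":
        w_live, w_dead = _gls_weights(live, dead, config)
    else:
        w_live = np.ones_like(live)
        w_dead = np.ones_like(dead)
    # prior sd of the three-frame anchor mean: per-point noise sd / sqrt(3)
    se_n0 = 1.0 / (w_live[:, ANCHOR_INDEX] * np.sqrt(3.0))
    se_d0 = 1.0 / (w_dead[:, ANCHOR_INDEX] * np.sqrt(3.0))

    def unpack(x):
        vals = dict(zip(free_shared, x[:ns]))
        kp = vals.get("k_p", 0.0)
        kd = vals.get("k_d", 0.0) if variant != 3 else 0.0
        v = vals.get("v", 0.0)
        if per_pair_kbys:
            kbys = x[ns : ns + P]
        else:
            kbys = vals.get("k_bys", 0.0) if variant != 1 else 0.0
        if fit_ics:
            ic_n0 = x[nk : nk + P]
            ic_d0 = x[nk + P : nk + 2 * P]
        else:
            ic_n0, ic_d0 = anchor_n0, anchor_d0
        return kp, kd, kbys, v, ic_n0, ic_d0

    def raw_residuals(x):
        kp, kd, kbys, v, ic_n0, ic_d0 = unpack(x)
        ml, md = _simulate_stacked(
            grid, ic_n0, ic_d0, g0, kp, kd, kbys, v,
            config.theta, config.g_star, config.g_min, config.cells_per_pct,
            config.ode_rtol, config.ode_atol, anchor=ANCHOR_INDEX,
        )
        if ml is None or not (np.all(np.isfinite(ml)) and np.all(np.isfinite(md))):
            return None
        return ml - live, md - dead

    def residual_fn(x):
        raw = raw_residuals(x)
        if raw is None:
            return big
        rl, rd = raw
        parts = [(w_live * rl).ravel(), (w_dead * rd).ravel()]
        if fit_ics:
            parts.append((x[nk : nk + P] - anchor_n0) / se_n0)
            parts.append((x[nk + P :] - anchor_d0) / se_d0)
        return np.concatenate(parts)

    jac_sparsity = None
    if P > 1 and (per_pair_kbys or fit_ics):
        S = sparse.lil_matrix((m_total, len(names)), dtype=int)
        S[:m, :ns] = 1
        for i in range(P):
            rows = np.concatenate(
                [np.arange(i * T, (i + 1) * T), m // 2 + np.arange(i * T, (i + 1) * T)]
            )
            if per_pair_kbys:
                S[rows, ns + i] = 1
            if fit_ics:
                S[rows, nk + i] = 1
                S[rows, nk + P + i] = 1
                S[m + i, nk + i] = 1
                S[m + P + i, nk + P + i] = 1
        jac_sparsity = S.tocsr()

    best = _multistart(residual_fn, names, config, jac_sparsity=jac_sparsity,
                       fixed_starts=fixed_starts)
    objective = float(2.0 * best.cost)
    raw = raw_residuals(best.x)
    raw_vec = (
        np.concatenate([raw[0].ravel(), raw[1].ravel()]) if raw is not None else best.fun[:m]
    )
    rss = float(raw_vec @ raw_vec)
    try:
        half = confidence_intervals(best.fun, best.jac)
    except NonIdentifiableError:
        half = np.full(len(names), np.inf)
    jac = best.jac.toarray() if sparse.issparse(best.jac) else np.asarray(best.jac)
    # reported free-parameter count covers the kinetic parameters; the
    # prior-tied initial-condition nuisances are penalized, not free
    return names[:nk], best, rss, objective, raw_vec, half[:nk], jac, m


def fit_local(pair: "TimeCoursePair", variant: int = 2,
              config: CalibrationConfig | None = None, weights=None) -> FitResult:
    """Calibrate all free kinetic parameters of one well independently."""
    config = config or CalibrationConfig()
    free = VARIANT_FREE[variant]
    names, best, rss, objective, raw, half, jac, m = _fit_pairs(
        [pair], variant, config, free, per_pair_kbys=False, weights=weights
    )
    return FitResult(
        estimates=dict(zip(names, map(float, best.x))),
        ci95=dict(zip(names, map(float, half))),
        rss=rss,
        residuals=raw,
        n_obs=m,
        scenario="local",
        variant=variant,
        well_id=pair.well_id,
        n_free=len(names),
        jacobian=jac,
        objective=objective,
    )


def fit_local_all(cohort: "Cohort", variant: int = 2,
                  config: CalibrationConfig | None = None, weights=None) -> list:
    """Independent local fits for every well of a cohort.

    ``weights``, when given, holds cohort-wide (w_live, w_dead) arrays; each
    well is fitted with its own rows so the pooled objective matches a joint
    fit's accounting.
    """
    fits = []
    for i, p in enumerate(cohort):
        w = None
        if weights is not None:
            w = (weights[0][i : i + 1], weights[1][i : i + 1])
        fits.append(fit_local(p, variant=variant, config=config, weights=w))
    return fits


def fit_global(cohort: "Cohort", variant: int = 2,
               config: CalibrationConfig | None = None, weights=None) -> FitResult:
    """One shared parameter vector minimizing the pooled objective."""
    config = config or CalibrationConfig()
    free = VARIANT_FREE[variant]
    names, best, rss, objective, raw, half, jac, m = _fit_pairs(
        list(cohort), variant, config, free, per_pair_kbys=False, weights=weights
    )
    return FitResult(
        estimates=dict(zip(names, map(float, best.x))),
        ci95=dict(zip(names, map(float, half))),
        rss=rss,
        residuals=raw,
        n_obs=m,
        scenario="global",
        variant=variant,
        n_free=len(names),
        jacobian=jac,
        objective=objective,
    )


def fit_mixed(cohort: "Cohort", variant: int = 2,
              config: CalibrationConfig | None = None, weights=None) -> MixedFit:
    """Jointly fit shared (k_p, k_d, v) plus one bystander rate per well.

    For variant 1 (no bystander term) the scenario degenerates to the global
    fit; the result then carries no per-well parameters.
    """
    config = config or CalibrationConfig()
    pairs = list(cohort)
    shared_names = MIXED_SHARED[variant]
    per_pair = variant != 1
    names, best, rss, objective, raw, half, jac, m = _fit_pairs(
        pairs, variant, config, shared_names, per_pair_kbys=per_pair, weights=weights
    )
    ns = len(shared_names)
    shared = FitResult(
        estimates=dict(zip(shared_names, map(float, best.x[:ns]))),
        ci95=dict(zip(shared_names, map(float, half[:ns]))),
        rss=rss,
        residuals=raw,
        n_obs=m,
        scenario="mixed",
        variant=variant,
        n_free=len(names),
        jacobian=jac,
        objective=objective,
    )
    locals_ = []
    if per_pair:
        T = len(pairs[0].times)
        for i, p in enumerate(pairs):
            rows = np.concatenate(
                [np.arange(i * T, (i + 1) * T), m // 2 + np.arange(i * T, (i + 1) * T)]
            )
            locals_.append(
                FitResult(
                    estimates={"k_bys": float(best.x[ns + i])},
                    ci95={"k_bys": float(half[ns + i])},
                    rss=float(raw[rows] @ raw[rows]),
                    residuals=raw[rows],
                    n_obs=2 * T,
                    scenario="mixed",
                    variant=variant,
                    well_id=p.well_id,
                    n_free=1,
                )
            )
    return MixedFit(
        shared=shared, locals_=locals_, rss=rss, n_obs=m, variant=variant,
        objective=objective,
    )
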