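"""Phenomenological laws linking the bystander death rate to initial conditions.

Per-well calibrations of the complete model yield one bystander death rate
k_bys per well.  Two empirical forms relate those estimates to the well's
initial conditions:

* surface:  k_bys = k_bys0 * N0 * exp(-alpha * G0)   (confluence-dependent)
* curve:    k_bys = k_bys0 * exp(-alpha * G0) + beta (confluence-independent)

where N0 is the initial cell abundance and G0 the initial glucose (mM).
The module is agnostic about N0's unit (cells or confluence %); the fitted
amplitude k_bys0 simply carries the reciprocal unit.  Fits are
inverse-variance-weighted nonlinear least squares using each sample's 95% CI
half-width; partial Pearson correlations quantify which initial conditions
k_bys actually depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares
from scipy import stats

from .calibrate import confidence_intervals

__all__ = [
    "BystanderLaw",
    "PartialCorrelation",
    "partial_correlation",
    "fit_surface",
    "fit_curve",
    "evaluate_law",
]


@dataclass(frozen=True)
class BystanderLaw:
    """A fitted bystander-rate law (surface or curve form) with 95% CIs.

    ``ci95`` maps parameter names to CI half-widths; ``flags`` records
    degeneracies detected during fitting (e.g. a glucose design that cannot
    constrain alpha).
    """

    form: str  # "surface" | "curve"
    k_bys0: float
    alpha: float
    beta: float | None = None
    ci95: dict = field(default_factory=dict)
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.form not in ("surface", "curve"):
            raise ValueError(f"form must be 'surface' or 'curve', got {self.form!r}")
        if self.k_bys0 < 0 or self.alpha < 0:
            raise ValueError("k_bys0 and alpha must be >= 0")
        if self.form == "curve":
            if self.beta is None or self.beta < 0:
                raise ValueError("curve form requires beta >= 0")
        elif self.beta is not None:
            raise ValueError("surface form takes no beta")

    @property
    def param_names(self) -> tuple:
        return ("k_bys0", "alpha") if self.form == "surface" else ("k_bys0", "alpha", "beta")

    def __call__(self, n0=None, g0=None):
        return evaluate_law(self, n0=n0, g0=g0)

    def to_json(self, path=None) -> str:
        payload = {
            "form": self.form,
            "estimates": {k: getattr(self, k) for k in self.param_names},
            "ci95": self.ci95,
            "flags": list(self.flags),
            "weights": "inverse squared 95% CI half-width",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "BystanderLaw":
        with open(path) as fh:
            payload = json.load(fh)
        est = payload["estimates"]
        return cls(
            form=payload["form"],
            k_bys0=est["k_bys0"],
            alpha=est["alpha"],
            beta=est.get("beta"),
            ci95=payload.get("ci95", {}),
            flags=tuple(payload.get("flags", ())),
        )


def evaluate_law(law: BystanderLaw, n0=None, g0=None):
    """Evaluate a law at initial conditions; vectorized, always >= 0.

    The surface form requires ``n0``; the curve form ignores it.
    """
    if g0 is None:
        raise ValueError("g0 is required")
    g0 = np.asarray(g0, dtype=float)
    if np.any(g0 < 0):
        raise ValueError("g0 must be >= 0")
    if law.form == "surface":
        if n0 is None:
            raise ValueError("surface form requires n0")
        n0 = np.asarray(n0, dtype=float)
        if np.any(n0 < 0):
            raise ValueError("n0 must be >= 0")
        out = law.k_bys0 * n0 * np.exp(-law.alpha * g0)
    else:
        out = law.k_bys0 * np.exp(-law.alpha * g0) + law.beta
    return float(out) if out.ndim == 0 else out


class PartialCorrelation(NamedTuple):
    r_n0: float
    p_n0: float
    r_g0: float
    p_g0: float


def _partial_r(x, y, z):
    """First-order Pearson partial correlation r(x, y | z) with its two-sided
    p-value (t reference with n - 3 degrees of freedom)."""
    r_xy = stats.pearsonr(x, y).statistic
    r_xz = stats.pearsonr(x, z).statistic
    r_yz = stats.pearsonr(y, z).statistic
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        return float("nan"), float("nan")
    r = float(np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0))
    dof = len(x) - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def partial_correlation(k_bys, n0, g0) -> PartialCorrelation:
    """First-order Pearson partial correlations of k_bys with each initial
    condition, controlling for the other.

    Returns r(k_bys, N0 | G0) and r(k_bys, G0 | N0) with two-sided p-values.
    """
    k_bys = np.asarray(k_bys, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    if not (len(k_bys) == len(n0) == len(g0)):
        raise ValueError("k_bys, n0, g0 must have equal length")
    if len(k_bys) < 4:
        raise ValueError("need >= 4 observations for a partial correlation")
    for name, arr in (("n0", n0), ("g0", g0), ("k_bys", k_bys)):
        if np.ptp(arr) == 0:
            raise ValueError(f"{name} is constant; partial correlation undefined")
    r_n0, p_n0 = _partial_r(k_bys, n0, g0)
    r_g0, p_g0 = _partial_r(k_bys, g0, n0)
    if np.isnan(r_n0) and np.isnan(r_g0):
        raise ValueError("both partial correlations are undefined for these data")
    return PartialCorrelation(r_n0=r_n0, p_n0=p_n0, r_g0=r_g0, p_g0=p_g0)


def _weights_from_ci(ci: np.ndarray) -> np.ndarray:
    """1/ci weights for residual scaling; zero half-widths are capped at the
    smallest nonzero one (unit weights if every half-width is zero)."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("CI half-widths must be >= 0")
    if np.all(ci == 0):
        return np.ones_like(ci)
    floor = ci[ci > 0].min()
    return 1.0 / np.maximum(ci, floor)


def _wnls(model, x0, k, w, bounds, x_scale):
    res = least_squares(
        lambda th: w * (model(th) - k),
        x0,
        bounds=bounds,
        method="trf",
        x_scale=x_scale,
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )
    if not res.success:
        raise RuntimeError(f"law fit failed to converge: {res.message}")
    return res


def fit_surface(n0, g0, k_bys, ci=None) -> BystanderLaw:
    """Fit the surface law k_bys = k_bys0 * N0 * exp(-alpha * G0).

    Weighted by inverse squared 95% CI half-widths of the k_bys samples
    (unit weights when ``ci`` is omitted).  Requires >= 3 samples spanning
    >= 2 glucose and >= 2 abundance levels; a single glucose level cannot
    identify alpha and raises.
    """
    n0 = np.asarray(n0, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    k = np.asarray(k_bys, dtype=float)
    if not (len(n0) == len(g0) == len(k)):
        raise ValueError("n0, g0, k_bys must have equal length")
    if len(k) < 3:
        raise ValueError("need >= 3 samples")
    if len(np.unique(g0)) < 2:
        raise ValueError("alpha non-identifiable: samples span a single glucose level")
    if len(np.unique(n0)) < 2:
        raise ValueError("surface fit needs >= 2 distinct abundance levels")
    w = _weights_from_ci(ci) if ci is not None else np.ones_like(k)

    flags = []
    if np.ptp(g0[g0 > 0]) == 0 and np.all(g0 == 0):  # pragma: no cover - guarded above
        flags.append("alpha-unconstrained")

    # initial guess: log-linear regression of k/N0 on G0 where positive
    pos = (k > 0) & (n0 > 0)
    if pos.sum() >= 2:
        slope, intercept, *_ = stats.linregress(g0[pos], np.log(k[pos] / n0[pos]))
        a0 = max(-slope, 1e-6)
        k0 = float(np.exp(intercept))
    else:
        a0, k0 = 0.1, max(k.max() / max(n0.max(), 1.0), 1e-12)

    def model(th):
        return th[0] * n0 * np.exp(-th[1] * g0)

    res = _wnls(model, [k0, a0], k, w, ([0.0, 0.0], [np.inf, np.inf]), [max(k0, 1e-12), max(a0, 1e-3)])
    half = confidence_intervals(res.fun, res.jac)
    return BystanderLaw(
        form="surface",
        k_bys0=float(res.x[0]),
        alpha=float(res.x[1]),
        ci95={"k_bys0": float(half[0]), "alpha": float(half[1])},
        flags=tuple(flags),
    )


def fit_curve(g0, k_bys, ci=None) -> BystanderLaw:
    """Fit the curve law k_bys = k_bys0 * exp(-alpha * G0) + beta.

    Requires >= 4 samples spanning >= 3 glucose levels.  A flat sample set
    degenerates to (k_bys0 -> 0, beta -> mean) and is flagged
    ``flat-law-degenerate``.
    """
    g0 = np.asarray(g0, dtype=float)
    k = np.asarray(k_bys, dtype=float)
    if len(g0) != len(k):
        raise ValueError("g0 and k_bys must have equal length")
    if len(k) < 4:
        raise ValueError("need >= 4 samples")
    if len(np.unique(g0)) < 3:
        raise ValueError("alpha non-identifiable: need >= 3 distinct glucose levels")
    w = _weights_from_ci(ci) if ci is not None else np.ones_like(k)

    kmax, kmin = float(k.max()), float(k.min())
    amp0 = max(kmax - kmin, 1e-12)
    b0 = max(kmin, 0.0)
    # decay guess from the glucose value where the excess halves
    excess = k - b0
    half_level = amp0 / 2.0
    above = g0[excess > half_level]
    g_half = float(above.max()) if above.size and above.max() > 0 else float(np.median(g0[g0 > 0]))
    a0 = np.log(2.0) / max(g_half, 1e-3)

    def model(th):
        return th[0] * np.exp(-th[1] * g0) + th[2]

    res = _wnls(
        model,
        [amp0, a0, b0],
        k,
        w,
        ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        [max(amp0, 1e-12), max(a0, 1e-3), max(b0, amp0, 1e-12)],
    )
    flags = []
    if res.x[0] <= 1e-10 * max(res.x[2], 1.0) or np.ptp(k) == 0:
        flags.append("flat-law-degenerate")
    try:
        half = confidence_intervals(res.fun, res.jac)
    except np.linalg.LinAlgError:
        half = [np.inf, np.inf, np.inf]
        flags.append("ci-degenerate")
    return BystanderLaw(
        form="curve",
        k_bys0=float(res.x[0]),
        alpha=float(res.x[1]),
        beta=float(res.x[2]),
        ci95={"k_bys0": float(half[0]), "alpha": float(half[1]), "beta": float(half[2])},
        flags=tuple(flags),
    )
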