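"""Coupled ODE model of tumor-cell growth under glucose limitation.

The state is (N, D, G): live-cell confluence (%), dead-cell confluence (%),
and glucose concentration (mM).  Live cells grow logistically toward a
carrying capacity, die of starvation when glucose runs low, and die of a
bystander effect proportional to the dead-cell fraction; glucose is consumed
with Michaelis-Menten kinetics.  Glucose-dependent state functions S_p and
S_d (which sum to one) partition the population's instantaneous fate between
proliferation and starvation death, with a tanh(t) factor delaying the onset
of glucose sensing after the medium change.

Three model variants form the selectable family:

* variant 1 -- no bystander death (k_bys terms removed),
* variant 2 -- the complete model,
* variant 3 -- no starvation death (k_d terms removed).

Units: time in days (t = 0 at medium change), abundances in confluence %,
glucose in mM.  The consumption rate ``v`` is a per-cell rate; an explicit
``cells_per_pct`` conversion (cells per confluence percent) links it to the
confluence-scale state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "CELLS_PER_PCT",
    "KineticParameters",
    "SystemState",
    "Trajectory",
    "IntegrationError",
    "state_death",
    "state_prolif",
    "rhs",
    "simulate",
    "term_contributions",
]

#: Cells per confluence percent in one well (~8e4 cells at 100% confluence
#: of a 96-well plate).  Converts the per-cell consumption rate v into a
#: per-confluence-percent rate; configurable wherever parameters are built.
CELLS_PER_PCT = 800.0

_VARIANTS = (1, 2, 3)


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic rates and fixed constants of the growth/death/consumption model.

    Parameters
    ----------
    k_p : float
        Maximum proliferation rate, day^-1.
    k_d : float
        Maximum starvation death rate, day^-1.
    k_bys : float
        Bystander-effect death rate, day^-1.
    v : float
        Glucose consumption rate per cell, mM.cell^-1.day^-1.
    theta : float
        Carrying capacity, confluence %.
    g_star : float
        Michaelis-Menten constant of consumption, mM.
    g_min : float
        Minimum glucose level for proliferation, mM.
    cells_per_pct : float
        Cells per confluence percent; converts v to the confluence scale.
    """

    k_p: float
    k_d: float
    k_bys: float
    v: float
    theta: float = 100.0
    g_star: float = 1.0
    g_min: float = 0.1
    cells_per_pct: float = CELLS_PER_PCT

    def __post_init__(self) -> None:
        for name in ("k_p", "k_d", "k_bys", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("theta", "g_star", "g_min", "cells_per_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def masked(self, variant: int) -> "KineticParameters":
        """Return parameters with the variant's excluded terms forced to zero."""
        _check_variant(variant)
        if variant == 1:
            return replace(self, k_bys=0.0)
        if variant == 3:
            return replace(self, k_d=0.0)
        return self


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: live %, dead %, glucose mM, time days."""

    n_live: float
    n_dead: float
    glucose: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_live", "n_dead", "glucose", "time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def y(self) -> np.ndarray:
        return np.array([self.n_live, self.n_dead, self.glucose], dtype=float)


@dataclass
class Trajectory:
    """Solution of the model on a time grid (days)."""

    times: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    glucose: np.ndarray
    params: KineticParameters | None = None
    variant: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.live = np.asarray(self.live, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if not (len(self.times) == len(self.live) == len(self.dead) == len(self.glucose)):
            raise ValueError("trajectory arrays must share one length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> SystemState:
        return SystemState(
            n_live=float(self.live[i]),
            n_dead=float(self.dead[i]),
            glucose=float(self.glucose[i]),
            time=float(self.times[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "live_pct": self.live,
                "dead_pct": self.dead,
                "glucose_mM": self.glucose,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["time_days"].to_numpy(),
            live=df["live_pct"].to_numpy(),
            dead=df["dead_pct"].to_numpy(),
            glucose=df["glucose_mM"].to_numpy(),
        )


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:g} d)")
        self.last_time = last_time


def _check_variant(variant: int) -> None:
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")


def _state_death_raw(glucose, time, g_min):
    g = np.asarray(glucose, dtype=float)
    return (1.0 - g / (g + g_min)) * np.tanh(time)


def state_death(glucose, time, g_min: float = 0.1):
    """Starvation-death state function S_d(G, t) = (1 - G/(G+G_min)) tanh(t).

    Lies in [0, 1): non-increasing in glucose at fixed time, non-decreasing
    in time at fixed glucose, and exactly 0 at t = 0 (the delay through which
    cells still sense their pre-medium-change glucose).
    """
    glucose = np.asarray(glucose, dtype=float)
    time = np.asarray(time, dtype=float)
    if g_min <= 0:
        raise ValueError(f"g_min must be > 0, got {g_min}")
    if np.any(glucose < 0) or np.any(time < 0):
        raise ValueError("glucose and time must be >= 0")
    out = _state_death_raw(glucose, time, g_min)
    return float(out) if out.ndim == 0 else out


def state_prolif(glucose, time, g_min: float = 0.1):
    """Proliferation state function S_p = 1 - S_d; in (0, 1]."""
    sd = state_death(glucose, time, g_min)
    return 1.0 - sd


def _rhs_arrays(t, n, d, g, p: KineticParameters):
    """Vectorized right-hand side on parallel arrays (no validation).

    Clips glucose at 0 so tiny negative solver excursions stay in-domain.
    Returns (dN, dD, dG, logistic, starvation, bystander) -- the last three
    are the signed components of dN/dt, reused by ``term_contributions``.
    """
    g = np.maximum(g, 0.0)
    sd = _state_death_raw(g, t, p.g_min)
    sp = 1.0 - sd
    logistic = p.k_p * n * (1.0 - n / p.theta) * sp
    starvation = p.k_d * n * sd
    den = n + d
    frac = np.divide(d, den, out=np.zeros_like(np.asarray(den, dtype=float)), where=den > 0)
    bystander = p.k_bys * n * frac
    dn = logistic - starvation - bystander
    dd = starvation + bystander
    dg = -p.v * p.cells_per_pct * n * g / (g + p.g_star)
    return dn, dd, dg, logistic, starvation, bystander


def rhs(state: SystemState, params: KineticParameters, variant: int = 2):
    """Time derivatives (dN/dt, dD/dt, dG/dt) for one state.

    The starvation and bystander death terms appear with opposite signs in
    dN/dt and dD/dt, so dN/dt + dD/dt equals the logistic term exactly: death
    only transfers mass from the live to the dead compartment.  At
    N = D = 0 the bystander fraction D/(D+N) is defined as 0.
    """
    p = params.masked(variant)
    dn, dd, dg, *_ = _rhs_arrays(
        state.time,
        np.float64(state.n_live),
        np.float64(state.n_dead),
        np.float64(state.glucose),
        p,
    )
    return float(dn), float(dd), float(dg)


def simulate(
    initial: SystemState,
    params: KineticParameters,
    variant: int = 2,
    grid: Sequence[float] | np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model on a time grid with an adaptive Runge-Kutta scheme.

    Parameters
    ----------
    initial : SystemState
        Initial condition; ``initial.time`` must equal ``grid[0]``.
    grid : array-like
        Strictly increasing output times in days (default: every 3 h over
        4 days, the imaging cadence this model was built for).

    Negative excursions smaller than 1e-9 in magnitude (solver noise around
    the absorbing N = 0 / G = 0 boundaries) are clipped to zero.
    """
    _check_variant(variant)
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a 1-d strictly increasing array of >= 2 times")
    if not np.isclose(initial.time, grid[0]):
        raise ValueError(f"initial.time ({initial.time}) must equal grid[0] ({grid[0]})")
    p = params.masked(variant)

    def fun(t, y):
        dn, dd, dg, *_ = _rhs_arrays(t, y[0], y[1], y[2], p)
        return (dn, dd, dg)

    sol = solve_ivp(
        fun,
        (grid[0], grid[-1]),
        initial.y,
        method="RK45",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(grid[0])
        raise IntegrationError(f"ODE integration failed: {sol.message}", last)
    y = sol.y
    y = np.where((y < 0) & (y > -1e-9), 0.0, y)
    return Trajectory(
        times=grid, live=y[0], dead=y[1], glucose=y[2], params=p, variant=variant
    )


def default_grid(dt_hours: float = 3.0, days: float = 4.0) -> np.ndarray:
    """The imaging grid: one point every `dt_hours` over `days` (33 points)."""
    n = int(round(days * 24.0 / dt_hours))
    return np.linspace(0.0, days, n + 1)


def term_contributions(
    trajectory: Trajectory,
    params: KineticParameters | None = None,
    at_times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Relative magnitudes of the three dN/dt terms along a trajectory.

    At each requested time returns |term_i| / sum_j |term_j| for the logistic
    growth, starvation death, and bystander death terms of the live-cell
    equation.  Where all three terms vanish (e.g. N = 0) the row is flagged
    ``defined = False`` and the fractions are reported as 0 rather than NaN.
    """
    p = params if params is not None else trajectory.params
    if p is None:
        raise ValueError("params must be given or stored on the trajectory")
    if trajectory.variant is not None:
        p = p.masked(trajectory.variant)
    times = trajectory.times if at_times is None else np.asarray(at_times, dtype=float)
    if at_times is not None:
        idx = [int(np.argmin(np.abs(trajectory.times - t))) for t in times]
        if not np.allclose(trajectory.times[idx], times):
            raise ValueError("at_times must be points of the trajectory grid")
    else:
        idx = np.arange(len(trajectory))
    n = trajectory.live[idx]
    d = trajectory.dead[idx]
    g = trajectory.glucose[idx]
    t = trajectory.times[idx]
    *_, logistic, starvation, bystander = _rhs_arrays(t, n, d, g, p)
    mags = np.abs(np.vstack([logistic, starvation, bystander]))
    total = mags.sum(axis=0)
    defined = total > 0
    safe = np.where(defined, total, 1.0)
    fr = mags / safe
    fr[:, ~defined] = 0.0
    return pd.DataFrame(
        {
            "time_days": t,
            "logistic": fr[0],
            "starvation": fr[1],
            "bystander": fr[2],
            "defined": defined,
        }
    )
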