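"""Model selection over (variant x calibration scenario) with small-sample AICc.

AICc = n ln(RSS) + 2p + 2p(p+1)/(n - p - 1)

balances goodness of fit against parameter count with a small-sample
correction.  Candidates are compared on one common data support: n counts
every live and dead residual of the cohort identically across candidates,
and p counts all free parameters of the candidate's scenario (local: the
variant's free parameters times the number of wells, on the pooled RSS;
global: the shared parameters; mixed: the shared parameters plus one k_bys
per well).  Ties break toward the smaller p, then declaration order.

RSS here is the minimized least-squares objective, computed with one
cohort-wide weight set shared by every candidate: under the default GLS
weighting it is the weighted residual sum of squares, which keeps the
comparison fair when the noise is strongly heteroscedastic (plain RSS lets
per-well parameters harvest the large noisy dead-cell values and biases the
criterion toward the most parameter-rich scenario).
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import pandas as pd

from .calibrate import (
    CalibrationConfig,
    CalibrationError,
    fit_global,
    fit_local_all,
    fit_mixed,
)

if TYPE_CHECKING:
    from .synth import Cohort

__all__ = ["aicc", "select_model", "DEFAULT_CANDIDATES"]

SCENARIOS = ("local", "global", "mixed")

#: The full candidate grid: three model variants x three scenarios.
DEFAULT_CANDIDATES = tuple(
    (variant, scenario) for variant in (1, 2, 3) for scenario in SCENARIOS
)


def aicc(rss: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    if rss <= 0:
        raise ValueError(f"rss must be > 0, got {rss}")
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    return n * math.log(rss) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _cohort_weights(cohort, config):
    """One cohort-wide weight set shared by every candidate.

    Commensurability across candidates requires scoring them on the same
    objective; under heteroscedastic multiplicative noise, the plain RSS
    over-rewards parameters that absorb high-variance (large, noisy dead)
    points, so the criterion operates on the GLS objective by default.
    """
    if config.weighting != "gls":
        return None
    from .calibrate import _gls_weights, _stack_pairs

    _, _, _, _, live, dead = _stack_pairs(list(cohort))
    return _gls_weights(live, dead, config)


def _run_candidate(cohort, variant, scenario, config, weights):
    if scenario == "local":
        fits = fit_local_all(cohort, variant=variant, config=config, weights=weights)
        rss = sum(f.objective for f in fits)
        p = sum(f.n_free for f in fits)
        n = sum(f.n_obs for f in fits)
        return rss, n, p
    if scenario == "global":
        fit = fit_global(cohort, variant=variant, config=config, weights=weights)
        return fit.objective, fit.n_obs, fit.n_free
    if scenario == "mixed":
        fit = fit_mixed(cohort, variant=variant, config=config, weights=weights)
        return fit.objective, fit.n_obs, fit.n_free
    raise ValueError(f"unknown scenario {scenario!r}")


def select_model(
    cohort: "Cohort",
    candidates: Sequence = DEFAULT_CANDIDATES,
    config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Calibrate every candidate and tabulate (rss, n, p, aicc).

    Returns a DataFrame with one row per candidate and a boolean ``selected``
    column flagging the minimal-AICc row.  A candidate whose calibration
    fails is kept with ``failed = True`` and excluded from selection; the
    result is invariant to candidate ordering (ties break toward smaller p,
    then declaration order).
    """
    config = config or CalibrationConfig()
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidates to select among")
    weights = _cohort_weights(cohort, config)
    rows = []
    for order, (variant, scenario) in enumerate(candidates):
        row = {"variant": variant, "scenario": scenario, "order": order,
               "rss": float("nan"), "n": 0, "p": 0, "aicc": float("nan"),
               "failed": False}
        try:
            rss, n, p = _run_candidate(cohort, variant, scenario, config, weights)
            row.update(rss=rss, n=n, p=p, aicc=aicc(rss, n, p))
        except (CalibrationError, ValueError) as exc:
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise CalibrationError("every candidate calibration failed")
    winner = ok.sort_values(["aicc", "p", "order"]).index[0]
    table["selected"] = False
    table.loc[winner, "selected"] = True
    return table.drop(columns="order")
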