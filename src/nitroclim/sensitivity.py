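"""Local-slope sensitivities of predicted loading to climate covariates.

Relative sensitivity is 100 x d ln(median load)/dx — the percent change in
loading per unit covariate change; absolute sensitivity is d(median load)/dx
in load units per covariate unit.  Slopes are central finite differences
with a 1-unit step (1 mm, 1 degC), so the numbers read directly as "% per
mm" / "% per degC".  Because the model is additive on the log scale, the
relative slope for a covariate does not depend on the other covariates,
while the absolute slope does (through the predicted level) — which is why
absolute temperature sensitivity grows with precipitation and absolute
precipitation sensitivity shrinks with warming.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd

from .gam import LoadGAM

__all__ = [
    "local_slope",
    "average_sensitivity",
    "sensitivity_curve",
    "SensitivityCurve",
    "SensitivitySummary",
]

DEFAULT_STEP = 1.0  # covariate units (mm or degC)


@dataclass(frozen=True)
class SensitivitySummary:
    covariate: str
    average: float  # % per unit
    low: float  # min over baselines
    high: float  # max over baselines
    n: int


@dataclass
class SensitivityCurve:
    target: str
    conditioning: str
    grid: np.ndarray
    slopes: pd.DataFrame  # one column per pin percentile
    scale: str


def _eval_ln_median(model: LoadGAM, base: pd.DataFrame) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return model.linear_predictor(base)


def local_slope(
    model: LoadGAM,
    covariate: str,
    at: pd.DataFrame,
    scale: str = "relative",
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Central-difference slope at each row of ``at``.

    relative : 100 * [ln q(x+h) - ln q(x-h)] / (2h)   (% per unit)
    absolute : [q(x+h) - q(x-h)] / (2h)               (load per unit)
    """
    if scale not in ("relative", "absolute"):
        raise ValueError("scale must be 'relative' or 'absolute'")
    lo = at.copy()
    hi = at.copy()
    lo[covariate] = lo[covariate] - step
    hi[covariate] = hi[covariate] + step
    eta_lo = _eval_ln_median(model, lo)
    eta_hi = _eval_ln_median(model, hi)
    if scale == "relative":
        return 100.0 * (eta_hi - eta_lo) / (2.0 * step)
    return (np.exp(eta_hi) - np.exp(eta_lo)) / (2.0 * step)


def average_sensitivity(
    model: LoadGAM,
    covariate: str,
    records: pd.DataFrame,
    step: float = DEFAULT_STEP,
) -> SensitivitySummary:
    """Training-distribution average of the relative local slope.

    Each record conditions the other covariates at its own values, so the
    average is over the covariate values actually observed historically.
    The (low, high) range is the min/max of the per-record slopes.
    """
    cols = [t.name for t in model.terms]
    slopes = local_slope(model, covariate, records[cols], "relative", step)
    return SensitivitySummary(
        covariate=covariate,
        average=float(np.mean(slopes)),
        low=float(np.min(slopes)),
        high=float(np.max(slopes)),
        n=len(slopes),
    )


def sensitivity_curve(
    model: LoadGAM,
    target: str,
    conditioning: str,
    pin_percentiles: tuple[float, float] = (50, 95),
    n_grid: int = 40,
    step: float = DEFAULT_STEP,
    scale: str = "absolute",
) -> SensitivityCurve:
    """Slope of ``target`` along a grid of ``conditioning`` values.

    The target covariate itself is pinned at its 50th and 95th training
    percentiles (one curve each); all remaining covariates sit at their
    training medians.  With an additive log model the *absolute* curves
    reproduce the cross-dependencies between precipitation and temperature
    sensitivities purely through the exponential back-transform.
    """
    pct = model.percentiles_
    if target not in pct.columns or conditioning not in pct.columns:
        raise KeyError(f"unknown covariate {target!r} or {conditioning!r}")
    lo, hi = model.support_[conditioning]
    grid = np.linspace(lo, hi, n_grid)
    medians = model.median_covariates()
    curves = {}
    for p in pin_percentiles:
        base = pd.DataFrame({k: np.full(n_grid, v) for k, v in medians.items()})
        base[conditioning] = grid
        base[target] = np.interp(
            p, pct.index.to_numpy(dtype=float), pct[target].to_numpy()
        )
        curves[f"p{p:g}"] = local_slope(model, target, base, scale, step)
    return SensitivityCurve(
        target=target,
        conditioning=conditioning,
        grid=grid,
        slopes=pd.DataFrame(curves, index=grid),
        scale=scale,
    )
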