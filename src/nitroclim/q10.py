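"""Equivalent denitrification Q10 from the fitted temperature response.

All nitrogen losses (surplus minus riverine loading, as areal yields in
kg N/ha/yr) are attributed to denitrification.  The loss curve

    L(t) = N_surplus,median - Q_median(t) / area_ha

is evaluated on t in [-2, 24] degC (0.5 degC steps) with every non-
temperature covariate pinned at its training median.  Q10(t) = L(t+5)/L(t-5)
for t in [3, 19]; the headline estimate is the average of Q10 weighted by
the probability density of training annual temperatures, and its
uncertainty range runs from Q10 at 19 degC down to Q10 at 3 degC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import LoadGAM

__all__ = ["loss_curve", "q10_at", "weighted_q10", "Q10Estimate"]

T_GRID = (-2.0, 24.0)
T_STEP = 0.5
Q10_RANGE = (3.0, 19.0)
HALF_WINDOW = 5.0


@dataclass
class Q10Estimate:
    q10: float  # temperature-pdf-weighted mean
    q10_low: float  # at t = 19 degC
    q10_high: float  # at t = 3 degC
    loss: pd.Series  # L(t), kg N/ha/yr, index t
    curve: pd.Series  # Q10(t), index t in [3, 19]


def loss_curve(
    model: LoadGAM,
    area_ha: float,
    surplus_median: float | None = None,
    temperature_col: str = "T_annual",
    t_grid: np.ndarray | None = None,
) -> pd.Series:
    """Nitrogen-loss yield versus temperature at median covariates.

    ``surplus_median`` defaults to exp of the training median of
    ``ln_Nsurplus``.  Raises if any loss is non-positive (the ratio would be
    meaningless).
    """
    if t_grid is None:
        t_grid = np.arange(T_GRID[0], T_GRID[1] + T_STEP / 2, T_STEP)
    medians = model.median_covariates()
    if surplus_median is None:
        if "ln_Nsurplus" not in medians:
            raise ValueError("surplus_median not given and ln_Nsurplus not in model")
        surplus_median = float(np.exp(medians["ln_Nsurplus"]))
    base = pd.DataFrame({k: np.full(len(t_grid), v) for k, v in medians.items()})
    base[temperature_col] = t_grid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        q_yield = np.exp(model.linear_predictor(base)) / area_ha
    loss = surplus_median - q_yield
    if np.any(loss <= 0):
        raise ValueError(
            "non-positive nitrogen losses on the temperature grid "
            f"(min {loss.min():.3g} kg N/ha/yr); surplus and loading scales "
            "are inconsistent"
        )
    return pd.Series(loss, index=t_grid, name="loss_kg_ha_yr")


def q10_at(loss: pd.Series, t: float) -> float:
    """Q10(t) = L(t+5)/L(t-5); t must lie in [3, 19] degC."""
    if not Q10_RANGE[0] <= t <= Q10_RANGE[1]:
        raise ValueError(f"t must be in [{Q10_RANGE[0]}, {Q10_RANGE[1]}] degC")
    grid = loss.index.to_numpy(dtype=float)
    vals = loss.to_numpy(dtype=float)
    hi = np.interp(t + HALF_WINDOW, grid, vals)
    lo = np.interp(t - HALF_WINDOW, grid, vals)
    return float(hi / lo)


def _q10_series(loss: pd.Series, step: float = T_STEP) -> pd.Series:
    ts = np.arange(Q10_RANGE[0], Q10_RANGE[1] + step / 2, step)
    return pd.Series([q10_at(loss, t) for t in ts], index=ts, name="q10")


def weighted_q10(
    loss: pd.Series,
    temperatures: np.ndarray,
    method: str = "empirical",
    bin_width: float = 1.0,
) -> Q10Estimate:
    """Temperature-pdf-weighted Q10 with its (19 degC, 3 degC) range.

    method="empirical" averages Q10 over the observed annual temperatures in
    [3, 19] (each observation a point mass); method="histogram" integrates
    Q10 against a fixed-bin histogram density by the trapezoid rule.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise ValueError("temperature sample is empty")
    curve = _q10_series(loss)
    inside = temperatures[
        (temperatures >= Q10_RANGE[0]) & (temperatures <= Q10_RANGE[1])
    ]
    if inside.size == 0:
        raise ValueError("no training temperatures fall in [3, 19] degC")
    if method == "empirical":
        grid = loss.index.to_numpy(dtype=float)
        q_at_obs = np.array([q10_at(loss, t) for t in inside])
        mean = float(np.mean(q_at_obs))
    elif method == "histogram":
        edges = np.arange(Q10_RANGE[0], Q10_RANGE[1] + bin_width, bin_width)
        dens, _ = np.histogram(inside, bins=edges, density=True)
        ts = curve.index.to_numpy()
        w = dens[np.clip(((ts - Q10_RANGE[0]) // bin_width).astype(int), 0, len(dens) - 1)]
        mean = float(np.trapezoid(curve.to_numpy() * w, ts) / np.trapezoid(w, ts))
    else:
        raise ValueError("method must be 'empirical' or 'histogram'")
    return Q10Estimate(
        q10=mean,
        q10_low=q10_at(loss, Q10_RANGE[1]),
        q10_high=q10_at(loss, Q10_RANGE[0]),
        loss=loss,
        curve=curve,
    )
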