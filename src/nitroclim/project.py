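"""Climate-to-loading projection: covariate derivation, effect decomposition,
ensemble statistics, and regional aggregation.

Per calendar year the climate covariates are: ``P_annual`` (sum of daily
precipitation, mm), ``T_annual`` (mean of the 12 monthly temperatures, degC)
and ``P_MAM_p95`` (total precipitation on March-May days whose amount
exceeds the reference-period 95th percentile of wet days, mm).  Relative
loading changes between a future window and the baseline window are computed
from period averages of yearly median predictions with non-climate
covariates pinned at current values; precipitation-only and temperature-only
changes replace only the corresponding covariates.  Ensemble medians,
sign-agreement robustness (80% rule), and precipitation/temperature tradeoff
classes summarize the member spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateSeries, PeriodDefinition
from .gam import LoadGAM

__all__ = [
    "derive_covariates",
    "project_member",
    "decompose_effects",
    "ensemble_stats",
    "aggregate_region",
    "project_ensemble",
    "CLIMATE_COVARIATES",
]

logger = logging.getLogger(__name__)

CLIMATE_COVARIATES = ("P_annual", "P_MAM_p95", "T_annual")
PRECIP_COVARIATES = ("P_annual", "P_MAM_p95")
WET_THRESHOLD = 0.1  # mm


def extreme_threshold(
    series: ClimateSeries,
    reference: tuple[int, int],
    percentile: float = 95.0,
    wet_threshold: float = WET_THRESHOLD,
) -> float:
    """Reference-period wet-day precipitation percentile (linear-interp convention)."""
    ref = series.subset(reference).precip.to_numpy()
    wet = ref[ref > wet_threshold]
    if wet.size == 0:
        return np.inf
    return float(np.percentile(wet, percentile))


def derive_covariates(
    series: ClimateSeries,
    reference: tuple[int, int],
    percentile: float = 95.0,
    wet_threshold: float = WET_THRESHOLD,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Yearly climate covariates from a daily/monthly series.

    Incomplete calendar years are omitted (logged).  ``threshold`` overrides
    the reference-period extreme-precipitation threshold (useful when the
    reference lies in a different series, e.g. observations).
    """
    thr = (
        extreme_threshold(series, reference, percentile, wet_threshold)
        if threshold is None
        else threshold
    )
    years = series.complete_years()
    all_years = series.years()
    if len(years) < len(all_years):
        dropped = sorted(set(all_years) - set(years))
        logger.info("omitting incomplete years: %s", dropped)
    p = series.precip
    by_year = p.groupby(p.index.year)
    p_annual = by_year.sum().reindex(years)
    mam = p[(p.index.month >= 3) & (p.index.month <= 5)]
    exceed = mam[mam > thr]
    p_mam = exceed.groupby(exceed.index.year).sum().reindex(years).fillna(0.0)
    t = series.temp
    t_annual = t.groupby(t.index.year).mean().reindex(years)
    return pd.DataFrame(
        {
            "P_annual": p_annual.to_numpy(dtype=float),
            "P_MAM_p95": p_mam.to_numpy(dtype=float),
            "T_annual": t_annual.to_numpy(dtype=float),
        },
        index=pd.Index(years, name="year"),
    )


# --------------------------------------------------------------------------
# member-level projection


def _period_mean_load(
    model: LoadGAM, climate: pd.DataFrame, fixed: dict[str, float]
) -> float:
    """Period average of yearly median load predictions."""
    X = climate.copy()
    for k, v in fixed.items():
        X[k] = v
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)  # extrapolation flagged upstream
        q = np.exp(model.linear_predictor(X))
    return float(np.mean(q))


def project_member(
    model: LoadGAM,
    baseline: pd.DataFrame,
    future: pd.DataFrame,
    fixed: dict[str, float],
) -> float:
    """Combined relative change (%) of period-average median load.

    ``baseline`` and ``future`` hold yearly climate covariates; ``fixed``
    pins the non-climate covariates (surplus, land use, tile drainage) at
    current values.
    """
    base = _period_mean_load(model, baseline, fixed)
    assert base > 0, "baseline average load must be positive"
    fut = _period_mean_load(model, future, fixed)
    return 100.0 * (fut - base) / base


def decompose_effects(
    model: LoadGAM,
    baseline: pd.DataFrame,
    future: pd.DataFrame,
    fixed: dict[str, float],
) -> tuple[float, float]:
    """Precipitation-only and temperature-only relative changes (%).

    P-only uses future P_annual/P_MAM_p95 with baseline temperature;
    T-only uses future temperature with baseline precipitation.  Windows
    may differ in length; covariates are paired by position after aligning
    each window's years in order (period averages are what matter).
    """
    base = _period_mean_load(model, baseline, fixed)
    n_b, n_f = len(baseline), len(future)
    if n_b == n_f:
        p_only = future.copy()
        p_only["T_annual"] = baseline["T_annual"].to_numpy()
        t_only = baseline.copy()
        t_only["T_annual"] = future["T_annual"].to_numpy()
    else:  # unequal windows: hold the other covariate at its period mean
        p_only = future.copy()
        p_only["T_annual"] = baseline["T_annual"].mean()
        t_only = baseline.copy()
        t_only["T_annual"] = future["T_annual"].mean()
    dq_p = 100.0 * (_period_mean_load(model, p_only, fixed) - base) / base
    dq_t = 100.0 * (_period_mean_load(model, t_only, fixed) - base) / base
    return dq_p, dq_t


# --------------------------------------------------------------------------
# ensemble statistics


@dataclass(frozen=True)
class EnsembleSummary:
    watershed_id: str
    scenario: str
    median_combined: float
    median_p_only: float
    median_t_only: float
    agreement: float
    robust: bool
    tradeoff_class: str


def _sign_agreement(values: np.ndarray, median: float) -> float:
    if median == 0:
        return float(np.mean(values == 0))
    return float(np.mean(np.sign(values) == np.sign(median)))


def classify_tradeoff(median_p_only: float, median_combined: float) -> str:
    """P/T tradeoff class: precipitation-driven increase offset by warming,
    compound decrease, or net increase."""
    if median_combined > 0:
        return "net-increase"
    if median_p_only > 0:
        return "offset"
    return "compound-decrease"


def ensemble_stats(results: pd.DataFrame) -> pd.DataFrame:
    """Per watershed x scenario: ensemble medians, 80% sign agreement, class.

    ``results`` has one row per (watershed_id, scenario, member) with columns
    ``dQ_combined``, ``dQ_P_only``, ``dQ_T_only``.
    """
    rows = []
    for (ws, scen), g in results.groupby(["watershed_id", "scenario"], sort=True):
        if len(g) < 2:
            raise ValueError("ensemble statistics need >= 2 members")
        comb = g["dQ_combined"].to_numpy(dtype=float)
        med_c = float(np.median(comb))
        med_p = float(np.median(g["dQ_P_only"].to_numpy(dtype=float)))
        med_t = float(np.median(g["dQ_T_only"].to_numpy(dtype=float)))
        agree = _sign_agreement(comb, med_c)
        rows.append(
            EnsembleSummary(
                ws, scen, med_c, med_p, med_t, agree, agree >= 0.80,
                classify_tradeoff(med_p, med_c),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def aggregate_region(
    baseline_loads: pd.DataFrame, future_loads: pd.DataFrame
) -> pd.DataFrame:
    """Load-weighted regional change per member, summarized over the ensemble.

    Inputs are watershed x member tables of period-average loads (same
    shape/labels).  Regional change per member is
    100 * (sum future - sum baseline) / sum baseline; the summary reports
    the member-wise changes plus their median and quartiles.
    """
    if baseline_loads.empty:
        raise ValueError("region is empty")
    if not baseline_loads.index.equals(future_loads.index) or not (
        baseline_loads.columns.equals(future_loads.columns)
    ):
        raise ValueError("baseline and future tables must align")
    if (baseline_loads.to_numpy() <= 0).any():
        raise ValueError("baseline loads must be positive")
    base = baseline_loads.sum(axis=0)
    fut = future_loads.sum(axis=0)
    change = 100.0 * (fut - base) / base
    q = np.percentile(change.to_numpy(), [25, 50, 75])
    summary = pd.DataFrame(
        {"dQ_region": change}
    )
    summary.attrs["median"] = float(q[1])
    summary.attrs["q25"] = float(q[0])
    summary.attrs["q75"] = float(q[2])
    return summary


# --------------------------------------------------------------------------
# end-to-end ensemble projection


def project_ensemble(
    model: LoadGAM,
    covariates: dict,
    fixed_by_watershed: dict[str, dict[str, float]],
    periods: PeriodDefinition,
    future_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Member-level changes for a corrected ensemble.

    ``covariates`` maps (watershed_id, scenario, member_id) -> yearly
    covariate DataFrame spanning baseline and future years.  Returns one row
    per key with combined / P-only / T-only changes.
    """
    fw = future_window or periods.mid_century
    rows = []
    for (ws, scen, member), cov in covariates.items():
        base = cov.loc[(cov.index >= periods.baseline[0]) & (cov.index <= periods.baseline[1])]
        fut = cov.loc[(cov.index >= fw[0]) & (cov.index <= fw[1])]
        fixed = fixed_by_watershed[ws]
        dq_c = project_member(model, base, fut, fixed)
        dq_p, dq_t = decompose_effects(model, base, fut, fixed)
        rows.append(
            {
                "watershed_id": ws,
                "scenario": scen,
                "member": member,
                "dQ_combined": dq_c,
                "dQ_P_only": dq_p,
                "dQ_T_only": dq_t,
            }
        )
    return pd.DataFrame(rows)
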