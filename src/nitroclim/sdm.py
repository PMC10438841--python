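"""Scaled distribution mapping (SDM) bias correction of climate ensembles.

SDM corrects each quantile of a model series against observations over a
common reference period while preserving the change the model projects
between its own reference and target periods: multiplicatively for daily
precipitation (gamma-distributed wet-day amounts, wet-day frequency
adjusted toward observed) and additively for monthly temperature (normal
fits per calendar month, linear trends removed before fitting and restored
afterwards).  Corrected reference-period distributions therefore match the
observations, and projected relative (precipitation) or absolute
(temperature) quantile changes survive the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateSeries

__all__ = [
    "ScaledDistributionMapper",
    "BiasCorrectionMap",
    "correct_ensemble",
]

logger = logging.getLogger(__name__)

WET_THRESHOLD = 0.1  # mm
MIN_REFERENCE_YEARS = 20


def _cdf_clamp(u: np.ndarray, n: int) -> np.ndarray:
    """Keep CDF values strictly inside (0, 1) so tail corrections stay finite.

    CDF values are always evaluated under the segment's own fitted
    distribution, so a tiny flat clamp is enough; gamma quantile ratios and
    normal quantile differences remain bounded in the tails."""
    del n
    eps = 1e-9
    return np.clip(u, eps, 1.0 - eps)


@dataclass
class _GammaFit:
    shape: float
    scale: float
    wet_frac: float
    n_wet: int

    @classmethod
    def from_series(cls, values: np.ndarray, wet_threshold: float) -> "_GammaFit":
        wet = values[values > wet_threshold]
        if wet.size < 10:
            raise ValueError("too few wet days to fit a gamma distribution")
        shape, _, scale = stats.gamma.fit(wet, floc=0.0)
        return cls(float(shape), float(scale), wet.size / values.size, wet.size)

    def cdf(self, x):
        return stats.gamma.cdf(x, self.shape, scale=self.scale)

    def ppf(self, u):
        return stats.gamma.ppf(u, self.shape, scale=self.scale)


@dataclass
class _NormalFit:
    mean: float
    sd: float
    slope: float  # linear trend per year, removed before fitting
    mid_year: float
    n: int

    @classmethod
    def from_series(cls, values: np.ndarray, years: np.ndarray, detrend: bool) -> "_NormalFit":
        slope = 0.0
        mid = float(np.mean(years))
        v = values
        if detrend and len(np.unique(years)) > 2:
            slope = float(np.polyfit(years, values, 1)[0])
            v = values - slope * (years - mid)
        return cls(float(np.mean(v)), float(max(np.std(v), 1e-9)), slope, mid, len(v))

    def cdf(self, x):
        return stats.norm.cdf(x, self.mean, self.sd)

    def ppf(self, u):
        return stats.norm.ppf(u, self.mean, self.sd)


@dataclass
class BiasCorrectionMap:
    """Reference-period distribution fits for one variable of one watershed.

    Precipitation maps are multiplicative (gamma wet-day fits plus wet-day
    frequencies); temperature maps are additive (per-calendar-month normal
    fits).  A map is fitted only on the declared reference period.
    """

    kind: str  # "precip" | "temp"
    reference: tuple[int, int]
    obs: object = None  # _GammaFit or dict[month, _NormalFit]
    mod: object = None

    @property
    def mode(self) -> str:
        return "multiplicative" if self.kind == "precip" else "additive"


class ScaledDistributionMapper:
    """SDM bias-correction estimator for one variable kind.

    Parameters
    ----------
    kind : {"precip", "temp"}
    reference : (int, int)
        Inclusive reference years (default 1981-2010).
    wet_threshold : float
        Precipitation at or below this (mm) counts as dry.
    detrend : bool
        Remove/restore linear temperature trends around the distribution fit.

    After :meth:`fit`, ``map_`` holds the fitted :class:`BiasCorrectionMap`;
    :meth:`transform` corrects any segment of the same model series.
    """

    def __init__(
        self,
        kind: str,
        reference: tuple[int, int] = (1981, 2010),
        wet_threshold: float = WET_THRESHOLD,
        detrend: bool = True,
    ):
        if kind not in ("precip", "temp"):
            raise ValueError("kind must be 'precip' or 'temp'")
        self.kind = kind
        self.reference = reference
        self.wet_threshold = wet_threshold
        self.detrend = detrend

    def get_params(self, deep=True):
        return {
            "kind": self.kind,
            "reference": self.reference,
            "wet_threshold": self.wet_threshold,
            "detrend": self.detrend,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------- fit

    def fit(self, obs: pd.Series, mod: pd.Series) -> "ScaledDistributionMapper":
        """Fit reference-period distributions for observations and model."""
        lo, hi = self.reference
        obs_ref = self._slice(obs, lo, hi)
        mod_ref = self._slice(mod, lo, hi)
        for name, s in (("observed", obs_ref), ("model", mod_ref)):
            yrs = np.unique(self._years(s))
            if len(yrs) < MIN_REFERENCE_YEARS:
                raise ValueError(
                    f"{name} series covers only {len(yrs)} reference years "
                    f"(< {MIN_REFERENCE_YEARS}); distribution fit unreliable"
                )
        if self.kind == "precip":
            o = _GammaFit.from_series(obs_ref.to_numpy(), self.wet_threshold)
            m = _GammaFit.from_series(mod_ref.to_numpy(), self.wet_threshold)
        else:
            o = self._monthly_fits(obs_ref)
            m = self._monthly_fits(mod_ref)
        self.map_ = BiasCorrectionMap(self.kind, self.reference, o, m)
        return self

    @staticmethod
    def _years(s: pd.Series) -> np.ndarray:
        return s.index.year.to_numpy() if hasattr(s.index, "year") else np.asarray(s.index)

    @staticmethod
    def _slice(s: pd.Series, lo: int, hi: int) -> pd.Series:
        yrs = s.index.year
        return s[(yrs >= lo) & (yrs <= hi)]

    def _monthly_fits(self, s: pd.Series) -> dict[int, _NormalFit]:
        return {
            m: _NormalFit.from_series(
                g.to_numpy(), g.index.year.to_numpy(), self.detrend
            )
            for m, g in s.groupby(s.index.month)
        }

    # ------------------------------------------------------------- transform

    def transform(self, segment: pd.Series) -> pd.Series:
        """Quantile-wise correction of one segment of the fitted model series."""
        if not hasattr(self, "map_"):
            raise RuntimeError("mapper is not fitted")
        if self.kind == "precip":
            return self._transform_precip(segment)
        return self._transform_temp(segment)

    def _transform_precip(self, segment: pd.Series) -> pd.Series:
        m: BiasCorrectionMap = self.map_
        obs: _GammaFit = m.obs
        ref: _GammaFit = m.mod
        x = segment.to_numpy(dtype=float)
        out = np.zeros_like(x)
        wet_mask = x > self.wet_threshold
        wet = x[wet_mask]
        if wet.size >= 10:
            seg = _GammaFit.from_series(x, self.wet_threshold)
            u = _cdf_clamp(seg.cdf(wet), seg.n_wet)
            # observed quantile scaled by the model-projected relative change
            corrected = obs.ppf(u) * (seg.ppf(u) / ref.ppf(u))
            # wet-day frequency adjusted toward observed: the driest corrected
            # wet days are zeroed when the model is too wet
            target_frac = min(seg.wet_frac * obs.wet_frac / max(ref.wet_frac, 1e-12), 1.0)
            n_target = int(round(target_frac * x.size))
            if n_target < wet.size:
                order = np.argsort(corrected)
                corrected[order[: wet.size - n_target]] = 0.0
            out[wet_mask] = np.maximum(corrected, 0.0)
        else:
            out[wet_mask] = wet  # too dry to refit; leave unchanged
        return pd.Series(out, index=segment.index, name=segment.name)

    def _transform_temp(self, segment: pd.Series) -> pd.Series:
        m: BiasCorrectionMap = self.map_
        out = pd.Series(index=segment.index, dtype=float, name=segment.name)
        for month, g in segment.groupby(segment.index.month):
            obs: _NormalFit = m.obs[month]
            ref: _NormalFit = m.mod[month]
            years = g.index.year.to_numpy()
            seg = _NormalFit.from_series(g.to_numpy(), years, self.detrend)
            v = g.to_numpy() - seg.slope * (years - seg.mid_year)
            u = _cdf_clamp(seg.cdf(v), seg.n)
            # observed quantile plus the model-projected absolute change
            corrected = obs.ppf(u) + (seg.ppf(u) - ref.ppf(u))
            out.loc[g.index] = corrected + seg.slope * (years - seg.mid_year)
        return out


# --------------------------------------------------------------------------
# ensemble driver


def correct_ensemble(
    obs: ClimateSeries,
    members,
    reference: tuple[int, int] = (1981, 2010),
    segments=((1950, 2014), (2015, 2099)),
    wet_threshold: float = WET_THRESHOLD,
) -> list[ClimateSeries]:
    """Fit and apply SDM per member for both variables over each segment.

    Members without full reference coverage are skipped with a logged
    reason.  Returns corrected :class:`ClimateSeries`, one per surviving
    member, in input order.
    """
    corrected = []
    for mem in members:
        series = mem.series if hasattr(mem, "series") else mem
        yrs = set(series.years())
        if not set(range(reference[0], reference[1] + 1)) <= yrs:
            logger.warning(
                "member %s lacks reference coverage; skipped",
                getattr(mem, "member_id", series.watershed_id),
            )
            continue
        pmap = ScaledDistributionMapper("precip", reference, wet_threshold).fit(
            obs.precip, series.precip
        )
        tmap = ScaledDistributionMapper("temp", reference).fit(obs.temp, series.temp)
        pparts, tparts = [], []
        for seg in segments:
            sub = series.subset(seg)
            if len(sub.precip) == 0:
                continue
            pparts.append(pmap.transform(sub.precip))
            tparts.append(tmap.transform(sub.temp))
        corrected.append(
            ClimateSeries(
                series.watershed_id, pd.concat(pparts), pd.concat(tparts)
            )
        )
    return corrected
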