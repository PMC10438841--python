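"""Daily-precipitation / monthly-temperature series container.

A :class:`ClimateSeries` holds, for one watershed, a calendar-complete daily
precipitation series (mm/day) and a monthly mean-temperature series (degC).
Period slicing is by calendar year; the conventional windows (reference
1981-2010, historical 1950-2014, future 2015-2099, baseline 1988-2017,
mid-century 2030-2059, late-century 2070-2099) live in
:class:`PeriodDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClimateSeries", "PeriodDefinition"]


@dataclass(frozen=True)
class PeriodDefinition:
    """Named analysis windows (inclusive year ranges)."""

    reference: tuple[int, int] = (1981, 2010)
    baseline: tuple[int, int] = (1988, 2017)
    mid_century: tuple[int, int] = (2030, 2059)
    late_century: tuple[int, int] = (2070, 2099)
    historical: tuple[int, int] = (1950, 2014)
    future: tuple[int, int] = (2015, 2099)

    def __post_init__(self):
        for name in ("reference", "baseline", "mid_century", "late_century"):
            lo, hi = getattr(self, name)
            if hi - lo + 1 != 30:
                raise ValueError(f"{name} window must span 30 years, got {lo}-{hi}")
        if self.mid_century[1] >= self.late_century[0]:
            raise ValueError("future windows must not overlap")


@dataclass
class ClimateSeries:
    """Per-watershed climate record.

    Attributes
    ----------
    watershed_id : str
    precip : pandas.Series
        Daily precipitation in mm, indexed by a unique, sorted DatetimeIndex.
    temp : pandas.Series
        Monthly mean temperature in degC, indexed by a monthly PeriodIndex.
    """

    watershed_id: str
    precip: pd.Series
    temp: pd.Series

    def __post_init__(self):
        if not isinstance(self.precip.index, pd.DatetimeIndex):
            self.precip = self.precip.copy()
            self.precip.index = pd.DatetimeIndex(self.precip.index)
        if not isinstance(self.temp.index, pd.PeriodIndex):
            self.temp = self.temp.copy()
            self.temp.index = pd.PeriodIndex(self.temp.index, freq="M")
        if self.precip.index.has_duplicates or not self.precip.index.is_monotonic_increasing:
            raise ValueError("precip index must be unique and sorted")
        if np.any(self.precip.to_numpy() < 0):
            raise ValueError("precipitation must be non-negative")

    # ----------------------------------------------------------------- slicing

    def years(self) -> np.ndarray:
        return np.unique(self.precip.index.year)

    def subset(self, years: tuple[int, int]) -> "ClimateSeries":
        """Inclusive calendar-year slice."""
        lo, hi = years
        p = self.precip[(self.precip.index.year >= lo) & (self.precip.index.year <= hi)]
        t = self.temp[(self.temp.index.year >= lo) & (self.temp.index.year <= hi)]
        return ClimateSeries(self.watershed_id, p, t)

    def complete_years(self) -> np.ndarray:
        """Years with a full daily calendar and all 12 monthly temperatures."""
        counts = self.precip.groupby(self.precip.index.year).size()
        full_days = counts.index[
            counts.to_numpy()
            >= np.where(pd.DatetimeIndex([f"{y}-12-31" for y in counts.index]).is_leap_year, 366, 365)
        ]
        tcounts = self.temp.groupby(self.temp.index.year).size()
        full_months = set(tcounts.index[tcounts == 12])
        return np.array(sorted(set(full_days) & full_months))

    def with_precip(self, precip: pd.Series) -> "ClimateSeries":
        return ClimateSeries(self.watershed_id, precip, self.temp.copy())

    def with_temp(self, temp: pd.Series) -> "ClimateSeries":
        return ClimateSeries(self.watershed_id, self.precip.copy(), temp)
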