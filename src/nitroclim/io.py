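"""CSV schemas and validated readers/writers for the pipeline tables.

All tabular artifacts are plain CSV.  Every file written here carries a
leading comment line ``# nitroclim seed=<s> config_sha256=<h>`` recording
the seed and configuration hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATCHMENT_COLUMNS",
    "read_catchment_table",
    "write_table",
    "read_table",
    "config_hash",
    "write_climate_series",
    "read_climate_series",
]

#: catchment-year table schema (documented units)
CATCHMENT_COLUMNS = {
    "catchment_id": "identifier",
    "year": "calendar year",
    "Q_TN": "annual N load, kg N/yr (> 0)",
    "P_annual": "annual precipitation, mm",
    "P_MAM_p95": "springtime extreme precipitation, mm",
    "T_annual": "annual mean temperature, degC",
    "ln_Nsurplus": "ln of annual N surplus (kg N/ha/yr)",
    "ln_Nsurplus_lag12": "ln of mean N surplus of the previous two years",
    "LU_D": "developed land, percent",
    "LU_C": "cultivated land, percent",
    "LU_FSH": "forest + shrubland, percent",
    "L_TD": "tile-drained land, percent",
}

_PCT_COLS = ("LU_D", "LU_C", "LU_FSH", "L_TD")


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if hasattr(config, "__dict__"):
        config = {k: v for k, v in vars(config).items()}
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_line(seed, config) -> str:
    return f"# nitroclim seed={seed} config_sha256={config_hash(config or {})}"


def write_table(df: pd.DataFrame, path, seed=0, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_line(seed, config) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_catchment_table(path) -> pd.DataFrame:
    """Typed, validated catchment-year records.

    Rows violating invariants (non-positive load, percentages outside
    [0, 100], extreme precipitation exceeding annual precipitation) are
    dropped with row-numbered log entries; a missing required column is a
    schema error.
    """
    df = read_table(path)
    missing = [c for c in CATCHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    ok = np.ones(len(df), dtype=bool)
    checks = [
        (df["Q_TN"].to_numpy(dtype=float) > 0, "Q_TN must be > 0"),
        (df["P_annual"].to_numpy(dtype=float) >= df["P_MAM_p95"].to_numpy(dtype=float), "P_annual < P_MAM_p95"),
        (df["P_MAM_p95"].to_numpy(dtype=float) >= 0, "P_MAM_p95 must be >= 0"),
    ]
    for col in _PCT_COLS:
        v = df[col].to_numpy(dtype=float)
        checks.append(((v >= 0) & (v <= 100), f"{col} outside [0, 100]"))
    for mask, reason in checks:
        bad = ~np.asarray(mask)
        for row in np.nonzero(bad & ok)[0]:
            logger.warning("row %d rejected: %s", row + 1, reason)
        ok &= ~bad
    if not ok.all():
        logger.info("rejected %d of %d rows", int((~ok).sum()), len(df))
    return df.loc[ok].reset_index(drop=True)


def write_climate_series(series, precip_path, temp_path, seed=0, config=None) -> None:
    p = series.precip.rename("precip_mm").reset_index()
    p.columns = ["date", "precip_mm"]
    p.insert(0, "watershed_id", series.watershed_id)
    write_table(p, precip_path, seed, config)
    t = series.temp.rename("temp_c").reset_index()
    t.columns = ["month", "temp_c"]
    t.insert(0, "watershed_id", series.watershed_id)
    t["year"] = [m.year for m in t["month"]]
    t["month"] = [m.month for m in t["month"]]
    write_table(t[["watershed_id", "year", "month", "temp_c"]], temp_path, seed, config)


def read_climate_series(precip_path, temp_path):
    from .climate import ClimateSeries

    p = read_table(precip_path)
    t = read_table(temp_path)
    wid = str(p["watershed_id"].iloc[0])
    precip = pd.Series(
        p["precip_mm"].to_numpy(dtype=float),
        index=pd.DatetimeIndex(p["date"]),
        name="precip_mm",
    )
    months = pd.PeriodIndex(
        [f"{y}-{m:02d}" for y, m in zip(t["year"], t["month"])], freq="M"
    )
    temp = pd.Series(t["temp_c"].to_numpy(dtype=float), index=months, name="temp_c")
    return ClimateSeries(wid, precip, temp)
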