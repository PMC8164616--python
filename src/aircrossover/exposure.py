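"""Exposure series: composite AQHI indices, daily 8-h maxima, and lagging.

The Air Quality Health Index (AQHI) is the Canadian composite of NO2, O3 and
PM2.5, built from excess-mortality risk coefficients estimated in large
Canadian cities.  AQHIX is the same construction with O3 replaced by the
daily maximum 8-h ozone (O3H8), emphasising ozone in the mixture.  Exposures
enter the case-crossover models lagged 0-14 days, weather lagged identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical pollutant identifiers and the units each is measured in.
POLLUTANT_UNITS = {
    "CO": "ppm",
    "NO2": "ppb",
    "O3": "ppb",
    "O3H8": "ppb",
    "PM25": "ug/m3",
    "SO2": "ppb",
    "AQHI": "index",
    "AQHIX": "index",
}

#: AQHI excess-risk coefficients (per ppb NO2/O3, per ug/m3 PM2.5) and the
#: conventional 10/10.4 x 100 scaling.  Overridable in every entry point.
AQHI_COEF_NO2 = 0.000871
AQHI_COEF_O3 = 0.000537
AQHI_COEF_PM25 = 0.000487
AQHI_SCALE = 10.0 / 10.4 * 100.0

MAX_LAG = 14


class ExposureError(ValueError):
    """Raised for malformed exposure inputs (dates, units, lags)."""


@dataclass
class ExposureSeries:
    """A daily concentration (or index) series for one pollutant.

    ``data`` is a float Series indexed by a strictly increasing daily
    DatetimeIndex; missing days are explicit NaN.  Negative concentrations
    are rejected -- an ambient concentration cannot be negative.
    """

    pollutant_id: str
    data: pd.Series
    units: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        idx = self.data.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ExposureError(
                    f"{self.pollutant_id}: dates must be consecutive daily and "
                    "strictly increasing"
                )
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ExposureError(f"{self.pollutant_id}: negative concentrations")
        if not self.units:
            self.units = POLLUTANT_UNITS.get(self.pollutant_id, "")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def compute_aqhi(no2, o3, pm25, *, c_no2: float = AQHI_COEF_NO2,
                 c_o3: float = AQHI_COEF_O3, c_pm25: float = AQHI_COEF_PM25,
                 scale: float = AQHI_SCALE):
    """Continuous (unrounded) AQHI from its three constituents.

    AQHI = scale * [(e^{c1*NO2} - 1) + (e^{c2*O3} - 1) + (e^{c3*PM2.5} - 1)]

    Inputs may be scalars or aligned array-likes in ppb (NO2, O3) and ug/m3
    (PM2.5).  Any missing constituent yields a missing index value for that
    day.  The operational 1-10+ integer rounding is deliberately not applied:
    the regression consumes the index on its continuous scale.
    """
    no2 = np.asarray(no2, dtype=float)
    o3 = np.asarray(o3, dtype=float)
    pm25 = np.asarray(pm25, dtype=float)
    for name, arr in (("NO2", no2), ("O3", o3), ("PM2.5", pm25)):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ExposureError(f"AQHI constituent {name} has negative values")
    out = scale * (np.expm1(c_no2 * no2) + np.expm1(c_o3 * o3)
                   + np.expm1(c_pm25 * pm25))
    return out if out.ndim else float(out)


def compute_aqhix(no2, o3h8, pm25, **kwargs):
    """AQHIX: the AQHI formula with O3 replaced by the daily max 8-h ozone."""
    return compute_aqhi(no2, o3h8, pm25, **kwargs)


def aqhi_series(no2: ExposureSeries, o3: ExposureSeries,
                pm25: ExposureSeries, *, use_o3h8: bool = False,
                **kwargs) -> ExposureSeries:
    """Build a daily AQHI (or AQHIX) ExposureSeries from constituent series."""
    df = pd.concat({"no2": no2.data, "o3": o3.data, "pm25": pm25.data}, axis=1)
    vals = compute_aqhi(df["no2"], df["o3"], df["pm25"], **kwargs)
    pid = "AQHIX" if use_o3h8 else "AQHI"
    return ExposureSeries(pid, pd.Series(vals, index=df.index), units="index")


def daily_max_8h(hourly: pd.Series, *, min_valid_hours: int = 6,
                 last_start_hour: int = 16) -> pd.Series:
    """Daily maximum running 8-h mean of an hourly series.

    For each calendar day the candidate windows start at hours
    00:00..``last_start_hour`` (17 windows, all inside the day).  A window is
    valid when at least ``min_valid_hours`` of its 8 hours are present, and
    its value is the mean of the present hours.  A day with no valid window
    is missing.

    ``hourly`` must be indexed by timestamps at exact 1-h resolution.
    """
    if not isinstance(hourly.index, pd.DatetimeIndex):
        raise ExposureError("hourly input must have a DatetimeIndex")
    idx = hourly.index
    if len(idx) and not ((idx.minute == 0).all() and (idx.second == 0).all()):
        raise ExposureError("hourly input must be at 1-h resolution")

    # Pivot to a (day x hour) grid; absent hours become NaN.
    frame = pd.DataFrame({"v": hourly.to_numpy(dtype=float)}, index=idx)
    frame["day"] = idx.normalize()
    frame["hour"] = idx.hour
    grid = frame.pivot_table(index="day", columns="hour", values="v",
                             aggfunc="mean")
    all_days = pd.DatetimeIndex(sorted(frame["day"].unique()))
    grid = grid.reindex(index=all_days, columns=range(24))
    arr = grid.to_numpy()

    n_days = arr.shape[0]
    best = np.full(n_days, np.nan)
    for start in range(last_start_hour + 1):
        win = arr[:, start:start + 8]
        n_ok = np.sum(np.isfinite(win), axis=1)
        total = np.nansum(win, axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n_ok >= min_valid_hours, total / n_ok, np.nan)
        best = np.fmax(best, mean)
    return pd.Series(best, index=grid.index, name="o3h8")


def lag_series(series: ExposureSeries, lag: int) -> ExposureSeries:
    """Shift a daily series so the value on date d is the original at d - lag.

    Lag 0 is the identity; the first ``lag`` days become missing.  Lags are
    restricted to the study's 0-14 day window.
    """
    if not (0 <= lag <= MAX_LAG):
        raise ExposureError(f"lag must be in [0, {MAX_LAG}], got {lag}")
    return ExposureSeries(series.pollutant_id, series.data.shift(lag),
                          units=series.units)


# ---------------------------------------------------------------------------
# CSV round-trip helpers (ISO dates, empty field = missing)

def write_daily_csv(series_map: dict[str, ExposureSeries], path) -> None:
    df = pd.concat({pid: s.data for pid, s in series_map.items()}, axis=1)
    df.index.name = "date"
    df.to_csv(path, date_format="%Y-%m-%d")


def read_daily_csv(path, units: dict[str, str] | None = None
                   ) -> dict[str, ExposureSeries]:
    df = pd.read_csv(path, index_col="date", parse_dates=True)
    units = units or {}
    return {
        col: ExposureSeries(col, df[col],
                            units=units.get(col, POLLUTANT_UNITS.get(col, "")))
        for col in df.columns
    }


def read_hourly_csv(path, value_col: str = "value") -> pd.Series:
    """Read an hourly series from a CSV with `date`, `hour` and value columns."""
    df = pd.read_csv(path, parse_dates=["date"])
    ts = df["date"] + pd.to_timedelta(df["hour"], unit="h")
    return pd.Series(df[value_col].to_numpy(dtype=float), index=pd.DatetimeIndex(ts))
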