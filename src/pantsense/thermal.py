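"""Thermal indices (THI, HLI), weather summaries and heat-event detection.

THI follows the NRC formulation on dry-bulb temperature (degC) and relative
humidity (%):

    THI = (1.8 T + 32) - (0.55 - 0.0055 RH) (1.8 T - 26)

HLI follows Gaughan's two-branch formulation on black-globe temperature
BG (degC), relative humidity RH (%) and wind speed WS (m/s):

    HLI = 8.62 + 0.38 RH + 1.55 BG - 0.5 WS + exp(2.4 - WS)   (BG >= 25)
    HLI = 10.66 + 0.28 RH + 1.3 BG - WS                       (BG <  25)

The printed pair of branches leaves BG = 25 uncovered; the hot branch is
used for BG >= 25, matching the original's treatment of the threshold as
part of the hot regime.  Both indices are dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _validate_rh(rh) -> np.ndarray:
    rh = np.asarray(rh, dtype=float)
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("relative humidity must lie in [0, 100] %")
    return rh


def thi(t_db, rh):
    """Temperature humidity index from dry-bulb temperature and humidity.

    Vectorised; scalars in give a scalar out.
    """
    rh = _validate_rh(rh)
    t_db = np.asarray(t_db, dtype=float)
    out = (1.8 * t_db + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t_db - 26.0)
    return out.item() if out.ndim == 0 else out


def hli(bg, rh, ws):
    """Heat load index from black-globe temperature, humidity and wind.

    Wind speed is in m/s; the hot-regime branch applies for bg >= 25 degC.
    """
    rh = _validate_rh(rh)
    bg = np.asarray(bg, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if (ws < 0).any():
        raise ValueError("wind speed must be non-negative")
    hot = 8.62 + 0.38 * rh + 1.55 * bg - 0.5 * ws + np.exp(2.4 - ws)
    cool = 10.66 + 0.28 * rh + 1.3 * bg - ws
    out = np.where(bg >= 25.0, hot, cool)
    return out.item() if out.ndim == 0 else out


def index_series(weather: pd.DataFrame) -> pd.DataFrame:
    """Attach ``thi`` and ``hli`` columns to a 10-minute weather frame.

    Expects columns ``timestamp, t_db, rh, bg, ws``.  Records lacking
    black-globe temperature yield a missing HLI (no fallback estimate).
    """
    out = weather.copy()
    out["thi"] = thi(out["t_db"].to_numpy(), out["rh"].to_numpy())
    bg = out["bg"].to_numpy(dtype=float)
    ok = ~np.isnan(bg)
    hli_vals = np.full(len(out), np.nan)
    if ok.any():
        hli_vals[ok] = hli(bg[ok], out["rh"].to_numpy()[ok], out["ws"].to_numpy()[ok])
    out["hli"] = hli_vals
    return out


def hourly_index_means(series: pd.DataFrame, columns=("thi", "hli")) -> pd.DataFrame:
    """Mean index value per clock hour, pooled across days.

    Empty hours are absent from the result (warned).
    """
    df = series.copy()
    df["hour"] = pd.DatetimeIndex(df["timestamp"]).hour
    out = df.groupby("hour")[list(columns)].mean()
    missing = sorted(set(range(24)) - set(out.index))
    if missing:
        logger.warning("no weather records for clock hour(s) %s", missing)
    return out


def hourly_means_by_day(series: pd.DataFrame, columns=("thi", "hli")) -> pd.DataFrame:
    """Mean index value per (date, hour) cell, for joining to hourly panting."""
    ts = pd.DatetimeIndex(series["timestamp"])
    df = series.assign(date=ts.date, hour=ts.hour)
    return df.groupby(["date", "hour"])[list(columns)].mean().reset_index()


def daily_summary(weather: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-day min/mean/max of temperature and humidity, plus across-day
    mean and sample SD of each daily statistic (n-1 denominator)."""
    ts = pd.DatetimeIndex(weather["timestamp"])
    df = weather.assign(date=ts.date)
    per_day = df.groupby("date")[["t_db", "rh"]].agg(["min", "mean", "max"])
    across = pd.concat(
        {"mean": per_day.mean(), "sd": per_day.std(ddof=1)}, axis=1
    )
    return {"per_day": per_day, "across_days": across}


@dataclass(frozen=True)
class HeatEvent:
    """A maximal run of >= min_days consecutive days on which the daily
    maxima of both THI and HLI reached the threshold."""

    start_day: date
    end_day: date
    n_days: int


def daily_maxima(series: pd.DataFrame) -> pd.DataFrame:
    """Daily maximum THI and HLI from a 10-minute index series."""
    ts = pd.DatetimeIndex(series["timestamp"])
    return series.assign(date=ts.date).groupby("date")[["thi", "hli"]].max()


def detect_heat_events(
    daily_max_thi: pd.Series,
    daily_max_hli: pd.Series,
    threshold: float = 90.0,
    min_days: int = 3,
) -> list[HeatEvent]:
    """Find heat events: runs of >= *min_days* consecutive calendar days
    whose daily maximum THI and HLI are both >= *threshold*.

    Both series must be indexed by the same calendar days.  Reported
    events are the maximal qualifying runs (disjoint, not overlapping
    sub-windows).
    """
    thi_s = daily_max_thi.sort_index()
    hli_s = daily_max_hli.sort_index()
    if not thi_s.index.equals(hli_s.index):
        raise ValueError("THI and HLI daily maxima cover different calendars")
    days = pd.DatetimeIndex(pd.to_datetime(thi_s.index))
    if len(days) == 0:
        return []
    qual = (thi_s.to_numpy() >= threshold) & (hli_s.to_numpy() >= threshold)
    # consecutive-calendar-day constraint: a gap in the calendar breaks a run
    contiguous = np.ones(len(days), dtype=bool)
    contiguous[1:] = (days[1:] - days[:-1]) == pd.Timedelta(days=1)
    events: list[HeatEvent] = []
    i = 0
    n = len(days)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1] and contiguous[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_days:
            events.append(
                HeatEvent(days[i].date(), days[j].date(), run_len)
            )
        i = j + 1
    return events
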