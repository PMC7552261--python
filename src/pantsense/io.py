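"""CSV readers and writers with validation.

File conventions: UTF-8, decimal point, ISO-8601 timestamps without
timezone (local time).  Minute-state files carry string state labels
(``panting``/``other``/``undefined``) and a blank or 0-4 panting score;
in memory, states are the integer codes of :mod:`pantsense.streams`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .streams import LABEL_STATES, STATE_LABELS, VALID_PS

logger = logging.getLogger(__name__)

MINUTE_COLUMNS = ["animal_id", "timestamp", "source", "state", "ps"]
WEATHER_COLUMNS = ["timestamp", "t_db_c", "rh_pct", "bg_c", "ws_ms", "solar_wm2", "rain_mm"]
ATTRIBUTE_COLUMNS = ["animal_id", "genotype", "coat", "sex", "weight_kg", "docility"]

_GENOTYPES = {"LT40_BI", "BI50"}
_COATS = {"dark", "tan", "white"}


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_minutes(path, source: str | None = None) -> pd.DataFrame:
    """Read a minute-state CSV into ``animal_id, minute, state, ps``.

    *source* optionally restricts to ``observer`` or ``sensor`` rows.
    Unknown state labels or panting scores are fatal, reported with their
    line number (header = line 1).
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        logger.warning("%s: empty minute file", path)
        return pd.DataFrame(columns=["animal_id", "minute", "state", "ps"])
    _require_columns(df, ["animal_id", "timestamp", "source", "state"], path)
    bad_state = ~df["state"].isin(LABEL_STATES)
    if bad_state.any():
        i = int(np.flatnonzero(bad_state)[0])
        raise FormatError(
            f"{path}: line {i + 2}: unknown state label {df['state'].iloc[i]!r}"
        )
    bad_source = ~df["source"].isin(("observer", "sensor"))
    if bad_source.any():
        i = int(np.flatnonzero(bad_source)[0])
        raise FormatError(
            f"{path}: line {i + 2}: unknown source {df['source'].iloc[i]!r}"
        )
    if "ps" in df.columns:
        ps = pd.to_numeric(df["ps"], errors="coerce")
        bad_ps = ps.notna() & ~ps.isin(VALID_PS)
        if bad_ps.any():
            i = int(np.flatnonzero(bad_ps)[0])
            raise FormatError(
                f"{path}: line {i + 2}: panting score {df['ps'].iloc[i]!r} "
                "outside 0-4"
            )
    else:
        ps = pd.Series(pd.NA, index=df.index)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "minute": pd.to_datetime(df["timestamp"]).dt.floor("min"),
            "source": df["source"],
            "state": df["state"].map(LABEL_STATES).astype(np.int8),
            "ps": ps.astype("Int8"),
        }
    )
    if source is not None:
        out = out[out["source"] == source].drop(columns="source").reset_index(drop=True)
    return out


def write_minutes(df: pd.DataFrame, path, source: str) -> None:
    """Write minute records (``animal_id, minute, state[, ps]``) to CSV."""
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "timestamp": pd.DatetimeIndex(df["minute"]).strftime("%Y-%m-%dT%H:%M"),
            "source": source,
            "state": df["state"].map(STATE_LABELS),
            "ps": df["ps"].astype("Int8") if "ps" in df.columns else pd.NA,
        }
    )
    out.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    """Read a 10-minute weather CSV into the internal column names."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty weather file", path)
        return pd.DataFrame(columns=["timestamp", "t_db", "rh", "bg", "ws", "solar", "rain"])
    _require_columns(df, ["timestamp", "t_db_c", "rh_pct"], path)
    out = pd.DataFrame({"timestamp": pd.to_datetime(df["timestamp"])})
    for src, dst in (
        ("t_db_c", "t_db"),
        ("rh_pct", "rh"),
        ("bg_c", "bg"),
        ("ws_ms", "ws"),
        ("solar_wm2", "solar"),
        ("rain_mm", "rain"),
    ):
        out[dst] = pd.to_numeric(df[src], errors="raise") if src in df.columns else np.nan
    bad_rh = (out["rh"] < 0) | (out["rh"] > 100)
    if bad_rh.any():
        i = int(np.flatnonzero(bad_rh)[0])
        raise FormatError(f"{path}: line {i + 2}: relative humidity outside [0, 100]")
    return out


def write_weather(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M"),
            "t_db_c": df["t_db"],
            "rh_pct": df["rh"],
            "bg_c": df["bg"],
            "ws_ms": df["ws"],
            "solar_wm2": df.get("solar", np.nan),
            "rain_mm": df.get("rain", np.nan),
        }
    )
    out.to_csv(path, index=False, float_format="%.3f")


def read_attributes(path) -> pd.DataFrame:
    """Read the animal-attribute CSV; categorical violations are fatal."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        logger.warning("%s: empty attribute file", path)
        return pd.DataFrame(columns=ATTRIBUTE_COLUMNS)
    _require_columns(df, ["animal_id", "genotype", "coat"], path)
    for col, allowed in (("genotype", _GENOTYPES), ("coat", _COATS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: line {i + 2}: {col} {df[col].iloc[i]!r} not in {sorted(allowed)}"
            )
    return df


def write_attributes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
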