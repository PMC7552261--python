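"""Minute-level behaviour-state streams.

An ear-tag sensor classifies each animal-minute as ``panting``, ``other``
(eating, ruminating, resting, activity) or ``undefined``.  Human observers
produce the same minute-level labels plus an ordinal panting score (PS).
This module holds the stream container, the observer/sensor alignment and
undefined-exclusion bookkeeping, the single-minute "fill" smoothing rule,
and run-length (bout) utilities.

States are stored as small integers (:data:`OTHER`, :data:`PANTING`,
:data:`UNDEFINED`) in NumPy ``int8`` arrays; the string labels used in CSV
files are mapped in :mod:`pantsense.io`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Behaviour-state codes.  Exactly three categories exist for sensor
#: streams; observer streams additionally carry a panting score.
OTHER: int = 0
PANTING: int = 1
UNDEFINED: int = 2

STATE_LABELS = {OTHER: "other", PANTING: "panting", UNDEFINED: "undefined"}
LABEL_STATES = {v: k for k, v in STATE_LABELS.items()}

#: Panting scores observed in this work (the full ethogram runs 0-4.5 but
#: scores above 2 were not recorded).  PS >= 1 implies the panting state.
VALID_PS = (0, 1, 2, 3, 4)

MINUTE = pd.Timedelta(minutes=1)


@dataclass
class StateStream:
    """Gap-free per-animal sequence of minute states.

    Parameters
    ----------
    animal_id
        Animal identifier.
    start
        Timestamp of the first minute (timezone-naive local time,
        truncated to whole minutes).
    states
        ``int8`` array of state codes, one per minute from ``start``.
    """

    animal_id: str
    start: pd.Timestamp
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).floor("min")
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = ~np.isin(self.states, (OTHER, PANTING, UNDEFINED))
        if bad.any():
            raise ValueError(
                f"invalid state code(s) {set(self.states[bad].tolist())} "
                f"for animal {self.animal_id}"
            )

    def __len__(self) -> int:
        return self.states.size

    @property
    def minutes(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq="min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "minute": self.minutes,
                "state": self.states,
            }
        )


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive minutes in one behaviour state."""

    animal_id: str
    state: int
    start_minute: pd.Timestamp
    duration_min: int


def fill_states(states: np.ndarray) -> np.ndarray:
    """Apply the single-minute fill rule to a state sequence.

    Scanning the *original* sequence left to right: once two consecutive
    minutes share the same defined state A, state A is "established" and
    every later minute is rewritten to A until two consecutive original
    minutes share a different defined state B, which then becomes the
    established state.  Minutes before the first such pair are unchanged.
    ``UNDEFINED`` minutes are opaque: they are never rewritten, never count
    towards a pair, and reset the established state (a fresh pair must form
    after them).  A trailing single minute with no following pair is filled
    with the established state, because the terminating condition ("until
    the next two consecutive records of a differing state") never occurs.

    The scan reads originals and writes to a copy, so filled values never
    establish or extend runs themselves.
    """
    s = np.asarray(states, dtype=np.int8)
    n = s.size
    if n == 0:
        return s.copy()
    idx = np.arange(n)
    defined = s != UNDEFINED
    # pair[i]: an establishing pair of identical defined states starts at i
    pair = np.zeros(n, dtype=bool)
    pair[:-1] = defined[:-1] & defined[1:] & (s[:-1] == s[1:])
    last_pair = np.maximum.accumulate(np.where(pair, idx, -1))
    last_undef = np.maximum.accumulate(np.where(~defined, idx, -1))
    established = (last_pair >= 0) & (last_pair > last_undef)
    out = s.copy()
    rewrite = defined & established
    out[rewrite] = s[last_pair[rewrite]]
    return out


def fill_transform(stream: StateStream) -> StateStream:
    """Return the fill-transformed copy of *stream* (timestamps unchanged)."""
    return StateStream(stream.animal_id, stream.start, fill_states(stream.states))


def to_bouts(stream: StateStream) -> list[Bout]:
    """Run-length encode a stream into maximal single-state bouts.

    Bouts are contiguous, non-overlapping and tile the stream: their
    durations sum to ``len(stream)``.
    """
    s = stream.states
    if s.size == 0:
        return []
    change = np.flatnonzero(s[1:] != s[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [s.size]))
    minutes = stream.minutes
    return [
        Bout(stream.animal_id, int(s[a]), minutes[a], int(b - a))
        for a, b in zip(starts, ends)
    ]


def bouts_to_states(bouts: list[Bout]) -> np.ndarray:
    """Decode bouts back into the state array (inverse of :func:`to_bouts`)."""
    return np.concatenate(
        [np.full(b.duration_min, b.state, dtype=np.int8) for b in bouts]
    ) if bouts else np.empty(0, dtype=np.int8)


def panting_minutes(stream: StateStream, start, end) -> int:
    """Count PANTING minutes in the half-open window ``[start, end)``.

    A window extending beyond the stream's coverage is counted over the
    covered intersection only, with a logged warning.
    """
    start = pd.Timestamp(start).floor("min")
    end = pd.Timestamp(end).floor("min")
    s0 = stream.start
    s1 = stream.start + len(stream) * MINUTE
    if start < s0 or end > s1:
        logger.warning(
            "window [%s, %s) extends outside stream coverage [%s, %s) "
            "for animal %s; counting over the intersection",
            start, end, s0, s1, stream.animal_id,
        )
    lo = max(0, int((start - s0) / MINUTE))
    hi = min(len(stream), int((end - s0) / MINUTE))
    if hi <= lo:
        return 0
    return int(np.count_nonzero(stream.states[lo:hi] == PANTING))


def _check_unique(df: pd.DataFrame, source: str) -> None:
    dup = df.duplicated(subset=["animal_id", "minute"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["animal_id", "minute"]]
        raise ValueError(
            f"duplicate (animal_id, minute) in {source} records: "
            f"({key['animal_id']}, {key['minute']})"
        )


def align_streams(observed: pd.DataFrame, sensor: pd.DataFrame) -> pd.DataFrame:
    """Join sensor states onto observed minutes by (animal_id, minute).

    Validation is restricted to observed minutes, so sensor-only minutes
    are dropped.  Observed minutes with no sensor record keep a missing
    ``sensor_state`` (and are later excluded alongside undefined minutes).

    Parameters
    ----------
    observed
        Columns ``animal_id, minute, state, ps``.
    sensor
        Columns ``animal_id, minute, state``.

    Returns
    -------
    DataFrame with columns ``animal_id, minute, observed_state,
    observed_ps, sensor_state`` (``sensor_state`` is a nullable integer).
    """
    obs = observed.rename(columns={"state": "observed_state", "ps": "observed_ps"})
    sen = sensor.rename(columns={"state": "sensor_state"})[
        ["animal_id", "minute", "sensor_state"]
    ]
    _check_unique(obs, "observer")
    _check_unique(sen, "sensor")
    merged = obs.merge(sen, on=["animal_id", "minute"], how="left")
    merged["sensor_state"] = merged["sensor_state"].astype("Int8")
    return merged


def exclude_undefined(aligned: pd.DataFrame):
    """Drop aligned minutes that are undefined (or absent) on either side.

    Returns ``(kept, n_excluded_total, n_excluded_sensor,
    n_excluded_observer)``.  A minute undefined on both sides is excluded
    once; the total is the size of the union while the per-source counts
    attribute each exclusion to the sensor and/or the observers.
    """
    sensor_bad = aligned["sensor_state"].isna() | (
        aligned["sensor_state"] == UNDEFINED
    )
    observer_bad = aligned["observed_state"].isna() | (
        aligned["observed_state"] == UNDEFINED
    )
    drop = (sensor_bad | observer_bad).to_numpy(dtype=bool)
    kept = aligned.loc[~drop].copy()
    kept["sensor_state"] = kept["sensor_state"].astype(np.int8)
    return (
        kept,
        int(drop.sum()),
        int(sensor_bad.sum()),
        int(observer_bad.sum()),
    )


def frame_to_streams(df: pd.DataFrame) -> dict[str, StateStream]:
    """Build per-animal gap-free :class:`StateStream` objects from a frame.

    The frame needs ``animal_id, minute, state`` columns; minutes of each
    animal must form a contiguous run (one record per minute).
    """
    streams: dict[str, StateStream] = {}
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("minute")
        minutes = pd.DatetimeIndex(grp["minute"])
        if len(minutes) > 1:
            deltas = np.diff(minutes.asi8)
            if (deltas <= 0).any():
                raise ValueError(f"duplicate minute for animal {animal_id}")
            if (deltas != 60_000_000_000).any():
                raise ValueError(
                    f"stream for animal {animal_id} has gaps; expected "
                    "one record per minute"
                )
        streams[str(animal_id)] = StateStream(
            str(animal_id), minutes[0], grp["state"].to_numpy(dtype=np.int8)
        )
    return streams
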