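"""Synthetic feedlot-herd generator.

Generates the four data tables the analysis pipeline consumes — 10-minute
weather, per-minute sensor behaviour states, focal-sampled observer
records, and animal attributes — together with the underlying truth, so
the whole pipeline can be exercised and its estimators checked against
known design parameters without any external data.

The generative model, briefly:

* Weather follows a diurnal piecewise-cosine temperature curve between a
  daily minimum (dawn) and maximum (mid-afternoon), with normally
  distributed day-to-day offsets; relative humidity moves in anti-phase;
  black-globe temperature adds a solar-driven daytime gain; wind speed is
  lognormal around its mean.
* Each animal carries a multiplicative susceptibility (frailty) drawn
  from a bounded scaled-Beta distribution with a designed between-animal
  coefficient of variation, plus additive genotype and coat-colour
  effects that act once the thermal load passes a designed THI onset.
  Minute states follow a two-state Markov chain whose stationary panting
  occupancy tracks the current propensity and whose mean panting-bout
  length is configurable.
* The sensor corrupts truth with per-minute misclassification: isolated
  (never adjacent within a run) single-minute flips at designed
  false-negative/false-positive rates — the error mode that motivates the
  fill rule — plus an optional independent base confusion and a small
  undefined rate.
* Two observers focal-sample animals in the 0800-1700 watch window for up
  to 15 minutes each, preferring currently panting animals, never
  observing the same animal twice in a day; windows may end early with
  the last minute recorded undefined.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` child streams, so a fixed seed reproduces
every table byte for byte.
"""

from __future__ import annotations

import logging

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import thermal
from .streams import OTHER, PANTING, UNDEFINED, StateStream

logger = logging.getLogger(__name__)

GENOTYPES = ("LT40_BI", "BI50")
COATS = ("dark", "tan", "white")
MINUTES_PER_DAY = 1440
RECORDS_PER_DAY = 144  # 10-minute cadence


@dataclass
class WeatherParams:
    """Diurnal weather process (defaults echo the study's summer feedlot:
    daily temperature min/max around 19/35 degC, humidity 30-85% in
    anti-phase, with a few degrees of day-to-day variation)."""

    t_min: float = 19.0
    t_max: float = 35.0
    day_sd: float = 3.0
    t_noise_sd: float = 0.3
    rh_at_tmin: float = 85.0
    rh_at_tmax: float = 30.0
    rh_noise_sd: float = 2.0
    bg_solar_gain: float = 12.0
    ws_mean: float = 2.0
    ws_sigma: float = 0.4
    hour_tmin: float = 5.0
    hour_tmax: float = 15.0


@dataclass
class PantingParams:
    """Thermal panting-response model.

    Occupancy (fraction of the hour spent panting) for animal *i* at
    minute *t* is::

        p_i(t) = clip(frailty_i * (base + ramp(THI_t)), 0, max_occupancy)
                 + hot_t * (genotype_i + coat_i)

    with ``ramp(THI) = slope * (THI - onset)_+ + quad * (THI - onset)_+^2``
    and ``hot_t = 1`` while THI exceeds ``onset + effect_onset_excess``
    (genotype and coat differences emerge once the heat load is
    substantial, not at the first sign of panting).  The effects are
    non-negative occupancy shifts (given in min/h) relative to the most
    heat-tolerant class, added outside the frailty product and below the
    ceiling headroom, so the designed group contrasts are never distorted
    by flooring or saturation.  Frailty has mean ~1 and a designed
    coefficient of variation on a bounded support; one spread parameter,
    shared by the genotype groups, is calibrated against the noise-free
    design day so the mean within-group CV of daily panting totals
    matches ``animal_cv`` (see ``_assign_frailty``).
    """

    base_occupancy: float = 0.083
    thi_onset: float = 64.0
    slope: float = 0.015
    quad: float = 0.0004
    genotype_gap_min: float = 3.0
    coat_effects_min: dict = field(
        default_factory=lambda: {"dark": 3.0, "tan": 1.5, "white": 0.0}
    )
    animal_cv: float = 0.8
    frailty_max: float = 4.0
    effect_onset_excess: float = 4.0
    mean_bout_min: float = 5.0
    max_occupancy: float = 0.60
    ps2_cut: float = 0.45


@dataclass
class SensorParams:
    """Per-minute sensor corruption.  ``flip_fn``/``flip_fp`` are the
    designed minute-level miss and false-alarm rates, implemented as
    isolated single-minute flips (so raw sensitivity = 1 - flip_fn and raw
    specificity = 1 - flip_fp); ``base_fn``/``base_fp`` add unstructured
    independent confusion on top when non-zero."""

    flip_fn: float = 0.40
    flip_fp: float = 0.20
    base_fn: float = 0.0
    base_fp: float = 0.0
    undefined_rate: float = 0.01


@dataclass
class ObserverParams:
    """Focal-sampling protocol: continuous observation in the watch
    window, up to 15 min per animal, preferring panting animals."""

    n_observers: int = 2
    max_window_min: int = 15
    watch_start_hour: int = 8
    watch_end_hour: int = 17
    panting_preference: float = 4.0
    end_early_prob: float = 0.05
    undefined_rate: float = 0.15


@dataclass
class HerdScenario:
    """Complete parameter set driving one synthetic study."""

    n_animals: int = 100
    days: int = 5
    start: str = "2019-01-10"
    genotype_mix: dict = field(
        default_factory=lambda: {"LT40_BI": 0.54, "BI50": 0.46}
    )
    coat_mix: dict = field(
        default_factory=lambda: {"dark": 0.525, "tan": 0.24, "white": 0.235}
    )
    sex_mix: dict = field(default_factory=lambda: {"steer": 0.205, "heifer": 0.795})
    weight_mean: float = 342.0
    weight_sd: float = 26.0
    docility_probs: tuple = (0.4, 0.3, 0.15, 0.1, 0.05)
    weather: WeatherParams = field(default_factory=WeatherParams)
    panting: PantingParams = field(default_factory=PantingParams)
    sensor: SensorParams = field(default_factory=SensorParams)
    observer: ObserverParams = field(default_factory=ObserverParams)
    seed: int = 20190110

    def __post_init__(self) -> None:
        for mix in (self.genotype_mix, self.coat_mix, self.sex_mix):
            total = sum(mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"mixture proportions sum to {total}, not 1")
        for p in (
            self.sensor.flip_fn,
            self.sensor.flip_fp,
            self.sensor.base_fn,
            self.sensor.base_fp,
            self.sensor.undefined_rate,
            self.observer.end_early_prob,
            self.observer.undefined_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.panting.mean_bout_min < 1.0:
            raise ValueError("mean bout length must be >= 1 minute")

    # -- named child RNG streams -------------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        order = ("weather", "attributes", "truth", "sensor", "observer")
        return np.random.Generator(
            np.random.PCG64(
                np.random.SeedSequence(
                    self.seed, spawn_key=(order.index(stream),)
                )
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "HerdScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("weather", WeatherParams),
            ("panting", PantingParams),
            ("sensor", SensorParams),
            ("observer", ObserverParams),
        ):
            if key in raw:
                raw[key] = sub(**raw[key])
        if "docility_probs" in raw:
            raw["docility_probs"] = tuple(raw["docility_probs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["docility_probs"] = list(raw["docility_probs"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _diurnal_fraction(hours: np.ndarray, h_min: float, h_max: float) -> np.ndarray:
    """0 at the daily temperature minimum, 1 at the maximum, cosine-shaped
    rise between them and cosine-shaped fall overnight."""
    rise = (hours - h_min) % 24.0
    rise_len = (h_max - h_min) % 24.0
    fall_len = 24.0 - rise_len
    frac = np.where(
        rise <= rise_len,
        0.5 - 0.5 * np.cos(np.pi * rise / rise_len),
        0.5 + 0.5 * np.cos(np.pi * (rise - rise_len) / fall_len),
    )
    return frac


def generate_weather(scenario: HerdScenario) -> pd.DataFrame:
    """Simulate the 10-minute on-site weather-station record.

    Returns columns ``timestamp, t_db, rh, bg, ws, solar, rain`` plus the
    derived ``thi``/``hli`` columns.
    """
    wp = scenario.weather
    rng = scenario.rng("weather")
    n = scenario.days * RECORDS_PER_DAY
    ts = pd.date_range(scenario.start, periods=n, freq="10min")
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    day_idx = np.repeat(np.arange(scenario.days), RECORDS_PER_DAY)
    day_offset = rng.normal(0.0, wp.day_sd, scenario.days)[day_idx]

    frac = _diurnal_fraction(hours, wp.hour_tmin, wp.hour_tmax)
    t_base = wp.t_min + (wp.t_max - wp.t_min) * frac
    t_db = t_base + day_offset + rng.normal(0.0, wp.t_noise_sd, n)
    rh = np.clip(
        wp.rh_at_tmin
        + (wp.rh_at_tmax - wp.rh_at_tmin) * frac
        + rng.normal(0.0, wp.rh_noise_sd, n),
        0.0,
        100.0,
    )
    solar_frac = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
    bg = t_db + wp.bg_solar_gain * solar_frac
    ws = wp.ws_mean * np.exp(
        rng.normal(0.0, wp.ws_sigma, n) - wp.ws_sigma**2 / 2.0
    )
    weather = pd.DataFrame(
        {
            "timestamp": ts,
            "t_db": t_db,
            "rh": rh,
            "bg": bg,
            "ws": ws,
            "solar": 1000.0 * solar_frac,
            "rain": 0.0,
        }
    )
    return thermal.index_series(weather)


# ---------------------------------------------------------------------------
# animals
# ---------------------------------------------------------------------------

def _design_day_thi(scenario: HerdScenario) -> np.ndarray:
    """Minute-resolution THI over the noise-free design reference day."""
    wp = scenario.weather
    hours = np.arange(MINUTES_PER_DAY) / 60.0
    frac = _diurnal_fraction(hours, wp.hour_tmin, wp.hour_tmax)
    t = wp.t_min + (wp.t_max - wp.t_min) * frac
    rh = np.clip(
        wp.rh_at_tmin + (wp.rh_at_tmax - wp.rh_at_tmin) * frac, 0.0, 100.0
    )
    return thermal.thi(t, rh)


def _effects_occ(scenario: HerdScenario, attributes: pd.DataFrame) -> np.ndarray:
    """Per-animal genotype + coat occupancy shift (applied while hot)."""
    pp = scenario.panting
    g_eff = np.where(
        attributes["genotype"].to_numpy() == "LT40_BI",
        pp.genotype_gap_min / 60.0,
        0.0,
    )
    c_eff = attributes["coat"].map(pp.coat_effects_min).to_numpy(dtype=float) / 60.0
    return g_eff + c_eff


def _assign_frailty(
    scenario: HerdScenario, attributes: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Designed per-animal susceptibility (frailty) vector.

    The frailty shape is a scaled Beta on [0, frailty_max] with mean 1,
    laid out on a quantile grid within each genotype group and shuffled —
    a designed population rather than an i.i.d. sample, so the designed
    group contrast and within-group spread are not blurred by chance
    imbalance at herd sizes of ~100.  The grid's spread is calibrated
    (per group, against the noise-free design reference day, including
    the occupancy ceiling and the group's coat composition) so that the
    design-curve coefficient of variation of daily panting totals equals
    ``animal_cv`` exactly.
    """
    pp = scenario.panting
    genotype = attributes["genotype"].to_numpy()
    n = len(genotype)
    if pp.animal_cv == 0:
        return np.ones(n)
    m = 1.0 / pp.frailty_max
    var = (pp.animal_cv / pp.frailty_max) ** 2
    if var >= m * (1 - m):
        raise ValueError("frailty CV too large for the configured maximum")
    s = m * (1 - m) / var - 1.0
    a, b = m * s, (1 - m) * s

    thi_d = _design_day_thi(scenario)
    excess = np.clip(thi_d - pp.thi_onset, 0.0, None)
    br = pp.base_occupancy + pp.slope * excess + pp.quad * excess**2
    hot_mins = float(
        (thi_d > pp.thi_onset + pp.effect_onset_excess).sum()
    )
    eff = _effects_occ(scenario, attributes)
    groups = [np.flatnonzero(genotype == g) for g in np.unique(genotype)]

    def group_grid(idx, kappa):
        q = (np.arange(idx.size) + 0.5) / idx.size
        lam0 = pp.frailty_max * stats.beta.ppf(q, a, b)
        return np.clip(1.0 + kappa * (lam0 - 1.0), 0.0, None)

    def design_cv_gap(kappa):
        # mean of the two within-group design CVs at this spread; the
        # same kappa is shared by both groups so the thermal-response
        # distribution is identical across genotypes and the designed
        # additive contrast is left untouched
        cvs = []
        for idx in groups:
            lam = group_grid(idx, kappa)
            totals = np.clip(
                lam[:, None] * br[None, :], 0.0, pp.max_occupancy
            ).sum(axis=1)
            e_min = eff[idx] * hot_mins  # designed effect minutes/day
            mean = totals.mean() + e_min.mean()
            v = totals.var(ddof=1) + e_min.var(ddof=1)
            cvs.append(np.sqrt(v) / mean)
        return float(np.mean(cvs)) - pp.animal_cv

    try:
        kappa = optimize.brentq(design_cv_gap, 0.05, 8.0)
    except ValueError:
        logger.warning(
            "frailty CV calibration out of range; using the uncalibrated grid"
        )
        kappa = 1.0
    frailty = np.empty(n)
    for idx in groups:
        frailty[idx] = rng.permutation(group_grid(idx, kappa))
    return frailty


def generate_attributes(scenario: HerdScenario) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the animal-attribute table and the hidden frailty vector.

    Frailty is part of the truth, never of the attribute table the
    pipeline sees.
    """
    rng = scenario.rng("attributes")
    n = scenario.n_animals
    ids = [f"A{i:03d}" for i in range(1, n + 1)]
    genotype = rng.choice(
        list(scenario.genotype_mix), p=list(scenario.genotype_mix.values()), size=n
    )
    coat = rng.choice(
        list(scenario.coat_mix), p=list(scenario.coat_mix.values()), size=n
    )
    sex = rng.choice(list(scenario.sex_mix), p=list(scenario.sex_mix.values()), size=n)
    weight = rng.normal(scenario.weight_mean, scenario.weight_sd, n).round(1)
    docility = rng.choice(
        np.arange(1, 6), p=np.asarray(scenario.docility_probs), size=n
    )
    attrs = pd.DataFrame(
        {
            "animal_id": ids,
            "genotype": genotype,
            "coat": coat,
            "sex": sex,
            "weight_kg": weight,
            "docility": docility,
        }
    )
    frailty = _assign_frailty(scenario, attrs, rng)
    return attrs, frailty


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class TruthData:
    """Per-animal-minute true states and panting scores.

    Retained alongside the emitted noisy tables for tests and recovery
    checks only; pipeline inputs never include it.
    """

    animal_ids: list
    start: pd.Timestamp
    states: np.ndarray = field(repr=False)  # (n_animals, n_minutes) int8
    ps: np.ndarray = field(repr=False)
    propensity: np.ndarray = field(repr=False)
    frailty: np.ndarray = field(repr=False)

    def streams(self) -> dict[str, StateStream]:
        return matrix_to_streams(self.animal_ids, self.start, self.states)

    def to_frame(self) -> pd.DataFrame:
        n_a, n_m = self.states.shape
        minutes = pd.date_range(self.start, periods=n_m, freq="min")
        return pd.DataFrame(
            {
                "animal_id": np.repeat(self.animal_ids, n_m),
                "minute": np.tile(minutes, n_a),
                "state": self.states.ravel(),
                "ps": self.ps.ravel(),
            }
        )


def matrix_to_streams(animal_ids, start, states: np.ndarray) -> dict[str, StateStream]:
    return {
        str(a): StateStream(str(a), start, states[i])
        for i, a in enumerate(animal_ids)
    }


def minute_thi(scenario: HerdScenario, weather: pd.DataFrame) -> np.ndarray:
    """THI interpolated from the 10-minute record onto the minute grid."""
    n_min = scenario.days * MINUTES_PER_DAY
    minutes = pd.date_range(scenario.start, periods=n_min, freq="min")
    t = pd.DatetimeIndex(weather["timestamp"]).asi8.astype(float)
    return np.interp(minutes.asi8.astype(float), t, weather["thi"].to_numpy())


def propensity_matrix(
    scenario: HerdScenario,
    thi_min: np.ndarray,
    attributes: pd.DataFrame,
    frailty: np.ndarray,
) -> np.ndarray:
    """Designed panting occupancy per animal-minute (rows follow the
    attribute table's animal order)."""
    pp = scenario.panting
    excess = np.clip(thi_min - pp.thi_onset, 0.0, None)
    ramp = pp.slope * excess + pp.quad * excess**2
    hot = (thi_min > pp.thi_onset + pp.effect_onset_excess).astype(float)
    p = np.clip(
        frailty[:, None] * (pp.base_occupancy + ramp[None, :]),
        0.0,
        pp.max_occupancy,
    ) + _effects_occ(scenario, attributes)[:, None] * hot[None, :]
    return np.clip(p, 0.0, 1.0)


def simulate_states(
    propensity: np.ndarray, mean_bout_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state Markov chain per animal whose stationary panting
    probability tracks the (possibly time-varying) propensity and whose
    mean panting-bout length is *mean_bout_min*."""
    n_a, n_m = propensity.shape
    q_exit = 1.0 / mean_bout_min
    states = np.empty((n_a, n_m), dtype=np.int8)
    u = rng.random((n_a, n_m))
    cur = (u[:, 0] < propensity[:, 0]).astype(np.int8)
    states[:, 0] = cur
    for t in range(1, n_m):
        p = propensity[:, t]
        q_entry = np.clip(q_exit * p / np.maximum(1.0 - p, 1e-12), 0.0, 1.0)
        stay = cur == PANTING
        nxt = np.where(stay, u[:, t] >= q_exit, u[:, t] < q_entry)
        cur = nxt.astype(np.int8)
        states[:, t] = cur
    return states


def generate_truth(
    scenario: HerdScenario,
    weather: pd.DataFrame,
    attributes: pd.DataFrame,
    frailty: np.ndarray,
) -> TruthData:
    """Simulate true per-minute behaviour states and panting scores."""
    rng = scenario.rng("truth")
    thi_min = minute_thi(scenario, weather)
    prop = propensity_matrix(scenario, thi_min, attributes, frailty)
    states = simulate_states(prop, scenario.panting.mean_bout_min, rng)
    ps = np.zeros_like(states)
    panting = states == PANTING
    ps[panting] = np.where(
        prop[panting] >= scenario.panting.ps2_cut, 2, 1
    ).astype(np.int8)
    return TruthData(
        animal_ids=attributes["animal_id"].tolist(),
        start=pd.Timestamp(scenario.start),
        states=states,
        ps=ps,
        propensity=prop,
        frailty=frailty,
    )


# ---------------------------------------------------------------------------
# sensor corruption
# ---------------------------------------------------------------------------

def _isolated_flip_mask(
    states: np.ndarray, q_fn: float, q_fp: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample single-minute flip positions that are never adjacent within
    a behaviour run, with exact per-minute marginal rates.

    Within each maximal run the first minute flips with probability q and
    each later minute with probability q/(1-q) provided its predecessor
    did not flip; by induction every minute's marginal flip probability is
    exactly q while adjacent within-run flips are impossible.
    """
    if q_fn >= 0.5 or q_fp >= 0.5:
        raise ValueError("isolated flip rates must be < 0.5 (adjacency-free)")
    n_a, n_m = states.shape
    q = np.where(states == PANTING, q_fn, q_fp)
    cond = q / (1.0 - q)
    u = rng.random((n_a, n_m))
    flips = np.zeros((n_a, n_m), dtype=bool)
    flips[:, 0] = u[:, 0] < q[:, 0]
    prev = flips[:, 0]
    for t in range(1, n_m):
        run_start = states[:, t] != states[:, t - 1]
        p_t = np.where(run_start, q[:, t], np.where(prev, 0.0, cond[:, t]))
        prev = u[:, t] < p_t
        flips[:, t] = prev
    return flips


def corrupt_to_sensor(
    truth: TruthData, scenario: HerdScenario
) -> np.ndarray:
    """Emit the sensor state matrix: base confusion, then isolated
    single-minute flips, then undefined minutes."""
    sp = scenario.sensor
    rng = scenario.rng("sensor")
    states = truth.states.copy()
    if sp.base_fn > 0 or sp.base_fp > 0:
        u = rng.random(states.shape)
        p_flip = np.where(states == PANTING, sp.base_fn, sp.base_fp)
        base = u < p_flip
        states[base] = (PANTING + OTHER) - states[base]
    if sp.flip_fn > 0 or sp.flip_fp > 0:
        flips = _isolated_flip_mask(states, sp.flip_fn, sp.flip_fp, rng)
        states[flips] = (PANTING + OTHER) - states[flips]
    if sp.undefined_rate > 0:
        undef = rng.random(states.shape) < sp.undefined_rate
        states[undef] = UNDEFINED
    return states


# ---------------------------------------------------------------------------
# observer focal sampling
# ---------------------------------------------------------------------------

def sample_observations(
    truth: TruthData, scenario: HerdScenario
) -> pd.DataFrame:
    """Simulate the two-observer focal-sampling protocol.

    Returns observer minute records (``animal_id, minute, state, ps``)
    restricted to the watch window.  Observers record the true state and
    panting score; a window that ends early has its last minute recorded
    as undefined, and further minutes are undefined at the configured
    rate.  The same animal is never observed twice on one day (by either
    observer).
    """
    op = scenario.observer
    rng = scenario.rng("observer")
    n_a, n_m = truth.states.shape
    records: list[tuple] = []
    minutes_index = pd.date_range(truth.start, periods=n_m, freq="min")
    for day in range(scenario.days):
        day_base = day * MINUTES_PER_DAY
        w0 = day_base + op.watch_start_hour * 60
        w1 = day_base + op.watch_end_hour * 60
        seen_today: set[int] = set()
        for _obs in range(op.n_observers):
            t = w0
            while t < w1:
                avail = np.array(
                    [i for i in range(n_a) if i not in seen_today], dtype=int
                )
                if avail.size == 0:
                    break
                w = 1.0 + op.panting_preference * (
                    truth.states[avail, t] == PANTING
                )
                animal = int(rng.choice(avail, p=w / w.sum()))
                seen_today.add(animal)
                max_len = min(op.max_window_min, w1 - t)
                if op.end_early_prob > 0:
                    drawn = int(rng.geometric(op.end_early_prob))
                else:
                    drawn = max_len
                length = min(max_len, drawn)
                ended_early = length < max_len
                for k in range(length):
                    state = int(truth.states[animal, t + k])
                    ps = int(truth.ps[animal, t + k])
                    undef = (k == length - 1 and ended_early) or (
                        rng.random() < op.undefined_rate
                    )
                    if undef:
                        state, ps = UNDEFINED, -1
                    records.append(
                        (
                            truth.animal_ids[animal],
                            minutes_index[t + k],
                            state,
                            ps,
                        )
                    )
                t += length
    df = pd.DataFrame(records, columns=["animal_id", "minute", "state", "ps"])
    df["ps"] = df["ps"].astype("Int8").where(df["ps"] >= 0)
    df["state"] = df["state"].astype(np.int8)
    return df


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    scenario: HerdScenario
    weather: pd.DataFrame
    attributes: pd.DataFrame
    truth: TruthData = field(repr=False)
    sensor_states: np.ndarray = field(repr=False)
    observations: pd.DataFrame = field(repr=False)

    def sensor_streams(self) -> dict[str, StateStream]:
        return matrix_to_streams(
            self.truth.animal_ids, self.truth.start, self.sensor_states
        )

    def sensor_frame(self) -> pd.DataFrame:
        n_a, n_m = self.sensor_states.shape
        minutes = pd.date_range(self.truth.start, periods=n_m, freq="min")
        return pd.DataFrame(
            {
                "animal_id": np.repeat(self.truth.animal_ids, n_m),
                "minute": np.tile(minutes, n_a),
                "state": self.sensor_states.ravel(),
            }
        )


def simulate_herd(
    scenario: HerdScenario, with_observers: bool = True
) -> SimulationResult:
    """Run the full generator for one scenario."""
    weather = generate_weather(scenario)
    attributes, frailty = generate_attributes(scenario)
    truth = generate_truth(scenario, weather, attributes, frailty)
    sensor = corrupt_to_sensor(truth, scenario)
    obs = (
        sample_observations(truth, scenario)
        if with_observers
        else pd.DataFrame(columns=["animal_id", "minute", "state", "ps"])
    )
    return SimulationResult(scenario, weather, attributes, truth, sensor, obs)
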