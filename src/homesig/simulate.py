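"""Synthetic single-occupant smart home event-stream generator.

The simulator emits event logs with the statistical structure the
analytics stack assumes: diurnal routines, weekend effects, linear trends,
changepoints, outlier days, keep-alive heartbeats and battery decay.
Impulsive sensors (toilet, fridge, door contact, PIR) are inhomogeneous
Poisson processes sampled by thinning against the day's maximum intensity;
state sensors (bed, chair, TV power) are session processes: a Poisson
number of sessions per day, start times drawn from a time-of-day density
and durations from a truncated normal (>= 1 min).

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import timedelta

import numpy as np
import pandas as pd
import yaml

from .events import EventLog, SensorSpec

__all__ = [
    "SessionModel",
    "RoutineProfile",
    "TrendSpec",
    "ChangepointSpec",
    "ScenarioSpec",
    "simulate_household",
    "make_change_scenario",
    "default_home_scenario",
    "scenario_specs",
    "planted_day_matrices",
    "block_prototype",
    "routine_prototype",
    "load_scenario",
]

N_BINS = 48  # 30-min bins per day
BIN_HOURS = 0.5


@dataclass(frozen=True)
class SessionModel:
    """Session process for a state sensor.

    ``start_density`` weights the 48 half-hour bins of the day for session
    start times; ``sessions_per_day`` is the Poisson mean of the daily
    session count; durations are normal, truncated at 1 minute.
    """

    sessions_per_day: float
    start_density: np.ndarray  # (48,) nonnegative weights
    mean_duration_min: float
    sd_duration_min: float
    power_level: float | None = None  # only for real_valued sensors (W)

    def __post_init__(self) -> None:
        d = np.asarray(self.start_density, dtype=float)
        if d.shape != (N_BINS,) or (d < 0).any() or d.sum() <= 0:
            raise ValueError("start_density must be 48 nonnegative weights")
        if self.sd_duration_min < 0:
            raise ValueError("session duration sd must be >= 0")
        object.__setattr__(self, "start_density", d)


@dataclass(frozen=True)
class RoutineProfile:
    """Daily routine of one sensor: an intensity curve or a session model."""

    sensor_id: str
    kind: str  # binary_state | impulsive | real_valued
    intensity: np.ndarray | None = None  # (48,) events/h, impulsive only
    session: SessionModel | None = None
    weekend_multiplier: float = 1.0
    binarize_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.weekend_multiplier <= 0:
            raise ValueError("weekend_multiplier must be > 0")
        if self.kind == "impulsive":
            if self.intensity is None:
                raise ValueError("impulsive routine requires an intensity vector")
            arr = np.asarray(self.intensity, dtype=float)
            if arr.shape != (N_BINS,) or (arr < 0).any():
                raise ValueError("intensity must be 48 nonnegative events/h values")
            object.__setattr__(self, "intensity", arr)
        elif self.kind in ("binary_state", "real_valued"):
            if self.session is None:
                raise ValueError(f"{self.kind} routine requires a session model")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def daily_rate(self) -> float:
        """Expected activations/day (impulsive) or sessions/day (state)."""
        if self.kind == "impulsive":
            return float(np.sum(self.intensity) * BIN_HOURS)
        return self.session.sessions_per_day


@dataclass(frozen=True)
class TrendSpec:
    """Linear ramp over the simulated window.

    ``total_change`` is the change, from first to last day, of the expected
    daily event count (impulsive) or of the expected daily active hours
    (state sensors).
    """

    sensor_id: str
    total_change: float


@dataclass(frozen=True)
class ChangepointSpec:
    sensor_id: str
    day: int
    routine: RoutineProfile


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a simulated household window."""

    days: int
    routines: tuple[RoutineProfile, ...]
    seed: int = 0
    start: pd.Timestamp = pd.Timestamp("2018-03-05T00:00:00Z")  # a Monday
    trends: tuple[TrendSpec, ...] = ()
    changepoints: tuple[ChangepointSpec, ...] = ()
    outlier_days: dict[int, float] = field(default_factory=dict)
    keepalive_interval: timedelta = timedelta(minutes=60)
    battery_decay_per_day: float = 0.45  # % / day, ~6-9 month life
    battery_noise_sd: float = 0.3
    gateway_id: str = "gw-01"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for cp in self.changepoints:
            if not (0 <= cp.day < self.days):
                raise ValueError("changepoint day index must be within the window")
        for day, scale in self.outlier_days.items():
            if scale <= 0:
                raise ValueError("outlier scale factor must be > 0")
            if not (0 <= day < self.days):
                raise ValueError("outlier day index must be within the window")


def scenario_specs(spec: ScenarioSpec) -> list[SensorSpec]:
    """SensorSpec list matching the scenario's sensors (for resampling)."""
    return [
        SensorSpec(
            sensor_id=r.sensor_id,
            kind=r.kind,
            binarize_threshold=r.binarize_threshold,
            keepalive_interval=spec.keepalive_interval,
        )
        for r in spec.routines
    ]


def _day_multiplier(
    spec: ScenarioSpec, routine: RoutineProfile, day: int, is_weekend: bool
) -> float:
    m = 1.0
    if is_weekend:
        m *= routine.weekend_multiplier
    if day in spec.outlier_days:
        m *= spec.outlier_days[day]
    return m


def _trend_factor(spec: ScenarioSpec, routine: RoutineProfile, day: int) -> float:
    """1 + relative ramp so that the daily expectation changes linearly."""
    for tr in spec.trends:
        if tr.sensor_id != routine.sensor_id:
            continue
        frac = day / (spec.days - 1) if spec.days > 1 else 0.0
        if routine.kind == "impulsive":
            base = routine.daily_rate
        else:
            base = (
                routine.session.sessions_per_day
                * routine.session.mean_duration_min
                / 60.0
            )  # expected hours/day
        if base <= 0:
            return 1.0
        return max(1.0 + (tr.total_change / base) * frac, 0.0)
    return 1.0


def _sample_impulsive_times(
    rng: np.random.Generator, intensity: np.ndarray, scale: float
) -> np.ndarray:
    """Inhomogeneous Poisson arrival times (hours in [0,24)) via thinning."""
    lam = intensity * scale
    lam_max = float(lam.max())
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * 24.0)
    t = np.sort(rng.uniform(0.0, 24.0, size=n))
    bins = np.minimum((t / BIN_HOURS).astype(int), N_BINS - 1)
    accept = rng.uniform(0.0, 1.0, size=n) < lam[bins] / lam_max
    return t[accept]


def _sample_sessions(
    rng: np.random.Generator,
    model: SessionModel,
    count_scale: float,
    duration_scale: float,
) -> list[tuple[float, float]]:
    """Sessions as (start_hour, duration_hours) within one day."""
    n = rng.poisson(model.sessions_per_day * count_scale)
    if n == 0:
        return []
    probs = model.start_density / model.start_density.sum()
    bins = rng.choice(N_BINS, size=n, p=probs)
    starts = (bins + rng.uniform(0.0, 1.0, size=n)) * BIN_HOURS
    durs = rng.normal(
        model.mean_duration_min * duration_scale,
        model.sd_duration_min * duration_scale,
        size=n,
    )
    durs = np.maximum(durs, 1.0) / 60.0
    return sorted(zip(starts.tolist(), durs.tolist()))


def _merge_sessions(sessions: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping (start, end) intervals (absolute hours)."""
    merged: list[list[float]] = []
    for s, e in sorted(sessions):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def simulate_household(spec: ScenarioSpec) -> EventLog:
    """Generate the event log of one simulated household window."""
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    start = spec.start
    routines_now = {r.sensor_id: r for r in spec.routines}
    cps = {(cp.sensor_id, cp.day): cp for cp in spec.changepoints}

    sessions_abs: dict[str, list[tuple[float, float]]] = {
        r.sensor_id: [] for r in spec.routines
    }

    for day in range(spec.days):
        day_start = start + timedelta(days=day)
        is_weekend = day_start.weekday() >= 5
        for r in spec.routines:
            cp = cps.get((r.sensor_id, day))
            if cp is not None:
                routines_now[r.sensor_id] = cp.routine
            routine = routines_now[r.sensor_id]
            mult = _day_multiplier(spec, routine, day, is_weekend)
            trend = _trend_factor(spec, routine, day)
            if routine.kind == "impulsive":
                times = _sample_impulsive_times(rng, routine.intensity, mult * trend)
                for t in times:
                    rows.append(
                        _status_row(spec, routine.sensor_id, day_start + timedelta(hours=float(t)), 1)
                    )
            else:
                # weekend/outlier multipliers scale how often; trends scale
                # how long (so daily active hours ramp linearly)
                for s, d in _sample_sessions(rng, routine.session, mult, trend):
                    t0 = day * 24.0 + s
                    sessions_abs[routine.sensor_id].append((t0, t0 + d))

    for r in spec.routines:
        if r.kind == "impulsive":
            continue
        level = None
        for candidate in (routines_now[r.sensor_id], r):
            if candidate.session and candidate.session.power_level is not None:
                level = candidate.session.power_level
                break
        for s, e in _merge_sessions(sessions_abs[r.sensor_id]):
            e = min(e, spec.days * 24.0)  # clip at window end
            if e <= s:
                continue
            t_on = start + timedelta(hours=s)
            t_off = start + timedelta(hours=e)
            if r.kind == "binary_state":
                rows.append(_status_row(spec, r.sensor_id, t_on, 1))
                rows.append(_status_row(spec, r.sensor_id, t_off, 0))
            else:  # real_valued: power reports at session edges
                rows.append(_power_row(spec, r.sensor_id, t_on, float(level or 0.0)))
                rows.append(_power_row(spec, r.sensor_id, t_off, 0.0))

    # keep-alives and daily battery reports per sensor
    total = timedelta(days=spec.days)
    n_ka = int(total / spec.keepalive_interval)
    for r in spec.routines:
        for i in range(n_ka):
            rows.append(
                {
                    "gtw_id": spec.gateway_id,
                    "obj_id": r.sensor_id,
                    "variable_id": "keepalive",
                    "ts": start + (i + 1) * spec.keepalive_interval,
                    "int_value": 1,
                    "float_value": None,
                    "string_value": None,
                    "flags": None,
                }
            )
        for day in range(spec.days):
            level = 100.0 - spec.battery_decay_per_day * day
            level += rng.normal(0.0, spec.battery_noise_sd)
            rows.append(
                {
                    "gtw_id": spec.gateway_id,
                    "obj_id": r.sensor_id,
                    "variable_id": "battery",
                    "ts": start + timedelta(days=day, hours=12),
                    "int_value": None,
                    "float_value": float(np.clip(level, 0.0, 100.0)),
                    "string_value": None,
                    "flags": None,
                }
            )

    frame = pd.DataFrame(rows)
    frame["ts"] = pd.to_datetime(frame["ts"], utc=True)
    frame["int_value"] = frame["int_value"].astype("Int64")
    frame["float_value"] = frame["float_value"].astype("float64")
    frame["gtw_id"] = frame["gtw_id"].astype("string")
    frame["obj_id"] = frame["obj_id"].astype("string")
    frame["variable_id"] = frame["variable_id"].astype("string")
    frame["string_value"] = frame["string_value"].astype("string")
    frame["flags"] = frame["flags"].astype("Int64")
    return EventLog(frame)


def _status_row(spec: ScenarioSpec, sensor: str, ts: pd.Timestamp, value: int) -> dict:
    return {
        "gtw_id": spec.gateway_id,
        "obj_id": sensor,
        "variable_id": "status",
        "ts": ts,
        "int_value": value,
        "float_value": None,
        "string_value": None,
        "flags": None,
    }


def _power_row(spec: ScenarioSpec, sensor: str, ts: pd.Timestamp, value: float) -> dict:
    return {
        "gtw_id": spec.gateway_id,
        "obj_id": sensor,
        "variable_id": "power",
        "ts": ts,
        "int_value": None,
        "float_value": value,
        "string_value": None,
        "flags": None,
    }


def make_change_scenario(
    base: ScenarioSpec, bins: set[int], relative_increase: float
) -> ScenarioSpec:
    """Second-period scenario with intensity scaled by ``1 + relative_increase``
    in the given 30-min bins only.

    Used as ground truth for profile-comparison power studies: the change is
    confined to a known time slot.  Applies to impulsive intensities and to
    state-sensor start densities.
    """
    if relative_increase <= -1:
        raise ValueError("relative_increase must be > -1")
    if not bins:
        return base
    bad = [b for b in bins if not (0 <= b < N_BINS)]
    if bad:
        raise ValueError(f"bin indices out of range: {bad}")
    mask = np.zeros(N_BINS)
    mask[sorted(bins)] = 1.0
    factor = 1.0 + relative_increase * mask
    new_routines = []
    for r in base.routines:
        if r.kind == "impulsive":
            new_routines.append(replace(r, intensity=r.intensity * factor))
        else:
            sess = replace(r.session, start_density=r.session.start_density * factor)
            new_routines.append(replace(r, session=sess))
    return replace(base, routines=tuple(new_routines))


def _bump(center_bin: float, width_bins: float, height: float) -> np.ndarray:
    """Gaussian bump over the 48 half-hour bins, wrapping at midnight."""
    x = np.arange(N_BINS, dtype=float)
    d = np.minimum(np.abs(x - center_bin), N_BINS - np.abs(x - center_bin))
    return height * np.exp(-0.5 * (d / width_bins) ** 2)


def block_prototype(
    spans: list[tuple[float, float]], hi: float = 0.95, lo: float = 0.02
) -> np.ndarray:
    """Near-deterministic habit profile: probability ``hi`` inside the given
    hour spans, ``lo`` elsewhere (48 half-hour bins)."""
    p = np.full(N_BINS, lo)
    for a, b in spans:
        p[int(a * 2) : int(b * 2)] = hi
    return p


def routine_prototype(bumps: list[tuple[float, float, float]]) -> np.ndarray:
    """Smooth day profile in [0,1] from (center_hour, width_hours, height) bumps."""
    prof = np.zeros(N_BINS)
    for center_h, width_h, height in bumps:
        prof += _bump(center_h * 2.0, max(width_h * 2.0, 0.5), height)
    return np.clip(prof, 0.0, 1.0)


def default_home_scenario(days: int = 30, seed: int = 0) -> ScenarioSpec:
    """The calibrated default household.

    A single occupant with bed/chair state sensors, toilet/fridge/door/PIR
    impulsive sensors and a TV power meter.  Intensities were frozen after
    calibrating by simulation to the field-reported order of magnitude
    (~130 status events/day, PIR contributing about half).
    """
    daytime = _bump(26, 10, 1.0) + 0.05  # broad daytime activity
    evening = _bump(41, 4, 1.0) + 0.01

    def imp(sensor: str, events_per_day: float, shape: np.ndarray) -> RoutineProfile:
        intensity = shape / (shape.sum() * BIN_HOURS) * events_per_day
        return RoutineProfile(sensor_id=sensor, kind="impulsive", intensity=intensity)

    routines = (
        RoutineProfile(
            sensor_id="bed",
            kind="binary_state",
            session=SessionModel(
                sessions_per_day=3.0,
                start_density=_bump(45, 2, 1.0) + _bump(28, 2, 0.35) + 1e-3,
                mean_duration_min=280.0,
                sd_duration_min=70.0,
            ),
        ),
        RoutineProfile(
            sensor_id="chair",
            kind="binary_state",
            session=SessionModel(
                sessions_per_day=10.0,
                start_density=daytime,
                mean_duration_min=40.0,
                sd_duration_min=18.0,
            ),
        ),
        imp("toilet", 12.0, daytime + _bump(6, 3, 0.3)),
        imp("fridge", 10.0, daytime),
        imp("door", 12.0, daytime),
        imp("pir", 62.0, daytime),
        RoutineProfile(
            sensor_id="tv",
            kind="real_valued",
            binarize_threshold=40.0,
            session=SessionModel(
                sessions_per_day=3.0,
                start_density=evening,
                mean_duration_min=90.0,
                sd_duration_min=30.0,
                power_level=80.0,
            ),
        ),
    )
    return ScenarioSpec(days=days, routines=routines, seed=seed)


def planted_day_matrices(
    prototypes: list[np.ndarray],
    n_days: int,
    noise_frac: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary day tensors drawn from planted routine prototypes.

    Each prototype is a (48, n_sensors) matrix of per-bin activation
    probabilities.  A fraction ``noise_frac`` of days is replaced by
    unstructured Bernoulli(0.3) noise and labelled -1.  Returns
    ``(days (n_days, 48, n_sensors), labels (n_days,))``; ground truth for
    habit-clustering recovery tests.
    """
    rng = np.random.default_rng(seed)
    protos = [np.asarray(p, dtype=float) for p in prototypes]
    shape = protos[0].shape
    if any(p.shape != shape for p in protos):
        raise ValueError("all prototypes must share one (bins, sensors) shape")
    labels = rng.integers(0, len(protos), size=n_days)
    noise = rng.uniform(size=n_days) < noise_frac
    labels = np.where(noise, -1, labels)
    days = np.empty((n_days,) + shape)
    for i in range(n_days):
        p = np.full(shape, 0.3) if labels[i] < 0 else protos[labels[i]]
        days[i] = (rng.uniform(size=shape) < p).astype(float)
    return days, labels


def load_scenario(path: str) -> ScenarioSpec:
    """Build a ScenarioSpec from a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    routines = []
    for r in doc["routines"]:
        session = None
        intensity = None
        if "session" in r:
            s = r["session"]
            session = SessionModel(
                sessions_per_day=float(s["sessions_per_day"]),
                start_density=np.asarray(s["start_density"], dtype=float),
                mean_duration_min=float(s["mean_duration_min"]),
                sd_duration_min=float(s["sd_duration_min"]),
                power_level=s.get("power_level"),
            )
        if "intensity" in r:
            intensity = np.asarray(r["intensity"], dtype=float)
        routines.append(
            RoutineProfile(
                sensor_id=r["sensor_id"],
                kind=r["kind"],
                intensity=intensity,
                session=session,
                weekend_multiplier=float(r.get("weekend_multiplier", 1.0)),
                binarize_threshold=r.get("binarize_threshold"),
            )
        )
    trends = tuple(
        TrendSpec(t["sensor_id"], float(t["total_change"]))
        for t in doc.get("trends", [])
    )
    outliers = {int(k): float(v) for k, v in (doc.get("outlier_days") or {}).items()}
    return ScenarioSpec(
        days=int(doc["days"]),
        routines=tuple(routines),
        seed=int(doc.get("seed", 0)),
        start=pd.Timestamp(doc.get("start", "2018-03-05T00:00:00Z")),
        trends=trends,
        outlier_days=outliers,
    )
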