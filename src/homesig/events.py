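"""Event schema, event-log I/O and signature-matrix resampling.

A smart home emits an irregular stream of sensor events (bed/chair/PIR
status changes, fridge or toilet activations, power-meter readings,
keep-alives, battery reports).  All downstream analytics operate on a
regularly-resampled *signature matrix*: a time x sensor array in which each
row is one resampling bin (default 1 minute) and each column one sensor.

Conventions
-----------
* All timestamps are stored and processed in UTC; a display timezone is a
  reporting-layer parameter only (e.g. daily aggregates).
* Bins are half-open ``[t, t + width)``, left-aligned to the epoch minute.
* A binary sensor's bin is active (1) iff the sensor was in the ON state
  during *any* instant of the bin ("any-overlap" rule); this preserves
  short events (fridge, toilet) at 1-min resolution.
* Real-valued sensors get the time-weighted mean of the reported step
  function within the bin; impulsive sensors get the activation count.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from datetime import timedelta, tzinfo
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "SensorSpec",
    "EventLog",
    "SignatureMatrix",
    "DailyAggregate",
    "SchemaError",
    "RowError",
    "read_event_log",
    "write_event_log",
    "resample_to_signature",
    "binarize_signature",
    "daily_aggregate",
]

#: Canonical column order of the flat event-log schema.
EVENT_COLUMNS = (
    "gtw_id",
    "obj_id",
    "variable_id",
    "ts",
    "int_value",
    "float_value",
    "string_value",
    "flags",
)

VARIABLE_IDS = ("status", "battery", "keepalive", "power")

SensorKind = Literal["binary_state", "impulsive", "real_valued"]


class SchemaError(ValueError):
    """The file does not match the expected event-log schema."""


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported instead of silently dropped."""

    line: int
    message: str


@dataclass(frozen=True)
class SensorSpec:
    """Static description of one sensor.

    Parameters
    ----------
    sensor_id:
        Identifier, unique within a gateway.
    kind:
        ``binary_state`` (bed, chair, door contact ...) for sensors with an
        ON/OFF state; ``impulsive`` (toilet, fridge, PIR) for sensors whose
        events are momentary activations; ``real_valued`` (power meter) for
        sensors reporting a measurement.
    binarize_threshold:
        For real-valued sensors, the level above which a bin counts as
        "active" when a binary signature matrix is requested.
    keepalive_interval:
        Expected heartbeat period even when the sensor is inactive.
    """

    sensor_id: str
    kind: SensorKind
    binarize_threshold: float | None = None
    keepalive_interval: timedelta = timedelta(minutes=60)

    def __post_init__(self) -> None:
        if self.kind not in ("binary_state", "impulsive", "real_valued"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")


@dataclass
class EventLog:
    """A validated, timestamp-sorted table of sensor events.

    ``frame`` has the columns of :data:`EVENT_COLUMNS` with ``ts`` as a
    timezone-aware UTC datetime.  ``errors`` collects malformed input rows
    (field logs are dirty; ingestion must not abort on a bad line).
    """

    frame: pd.DataFrame
    errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"event frame missing columns: {missing}")
        self.frame = self.frame.loc[:, list(EVENT_COLUMNS)].sort_values(
            "ts", kind="stable"
        )
        self.frame.reset_index(drop=True, inplace=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        if len(self.frame) == 0:
            raise ValueError("empty event log has no span")
        return self.frame["ts"].iloc[0], self.frame["ts"].iloc[-1]

    def for_sensor(self, sensor_id: str, variable_id: str | None = None) -> pd.DataFrame:
        sel = self.frame["obj_id"] == sensor_id
        if variable_id is not None:
            sel &= self.frame["variable_id"] == variable_id
        return self.frame.loc[sel]


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gtw_id": pd.Series(dtype="string"),
            "obj_id": pd.Series(dtype="string"),
            "variable_id": pd.Series(dtype="string"),
            "ts": pd.Series(dtype="datetime64[ns, UTC]"),
            "int_value": pd.Series(dtype="Int64"),
            "float_value": pd.Series(dtype="float64"),
            "string_value": pd.Series(dtype="string"),
            "flags": pd.Series(dtype="Int64"),
        }
    )


def _validate_row(row: dict, specs_by_id: dict[str, SensorSpec]) -> str | None:
    """Return an error message for a malformed row, or None if valid."""
    vid = row.get("variable_id")
    if vid not in VARIABLE_IDS:
        return f"unknown variable_id {vid!r}"
    if pd.isna(row["ts"]):
        return "unparseable timestamp"
    spec = specs_by_id.get(row.get("obj_id"))
    has_int = row.get("int_value") is not None and not pd.isna(row["int_value"])
    has_float = row.get("float_value") is not None and not pd.isna(row["float_value"])
    if vid == "status" and spec is not None:
        if spec.kind in ("binary_state", "impulsive"):
            if has_int and has_float:
                return "both int_value and float_value set for a binary sensor"
            if not has_int:
                return "status event of a binary sensor requires int_value"
            if int(row["int_value"]) not in (0, 1):
                return f"binary status must be 0/1, got {row['int_value']}"
        elif spec.kind == "real_valued" and vid == "status" and not has_float:
            return "status of a real-valued sensor requires float_value"
    if vid == "power" and not has_float:
        return "power event requires float_value"
    if has_float and not np.isfinite(row["float_value"]):
        return "float_value must be finite"
    return None


def read_event_log(
    path: str | Path | io.TextIOBase,
    specs: Sequence[SensorSpec] = (),
) -> EventLog:
    """Read a CSV or JSONL event log into a validated :class:`EventLog`.

    Malformed rows are reported in ``EventLog.errors`` with their line
    number; they never abort ingestion.  A missing mandatory column raises
    :class:`SchemaError`.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        text = p.read_text()
        is_jsonl = p.suffix.lower() in (".jsonl", ".ndjson")
    else:
        text = path.read()
        is_jsonl = text.lstrip()[:1] == "{"

    specs_by_id = {s.sensor_id: s for s in specs}

    if is_jsonl:
        records, errors = [], []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                errors.append(RowError(lineno, f"invalid JSON: {exc}"))
                continue
            records.append((lineno, rec))
        raw = pd.DataFrame([r for _, r in records])
        lines = [ln for ln, _ in records]
        if len(raw) == 0:
            return EventLog(_empty_frame(), errors)
        missing = [c for c in ("obj_id", "variable_id", "ts") if c not in raw.columns]
        if missing:
            raise SchemaError(f"missing mandatory keys: {missing}")
    else:
        raw = pd.read_csv(io.StringIO(text), dtype="object")
        missing = [c for c in ("obj_id", "variable_id", "ts") if c not in raw.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        lines = list(range(2, len(raw) + 2))  # header is line 1
        errors = []

    for col in EVENT_COLUMNS:
        if col not in raw.columns:
            raw[col] = None

    ts = pd.to_datetime(raw["ts"], errors="coerce", utc=True, format="ISO8601")
    int_v = pd.to_numeric(raw["int_value"], errors="coerce").astype("Int64")
    float_v = pd.to_numeric(raw["float_value"], errors="coerce").astype("float64")
    flags = pd.to_numeric(raw["flags"], errors="coerce").astype("Int64")

    keep = []
    for i in range(len(raw)):
        row = {
            "gtw_id": raw["gtw_id"].iloc[i],
            "obj_id": raw["obj_id"].iloc[i],
            "variable_id": raw["variable_id"].iloc[i],
            "ts": ts.iloc[i],
            "int_value": int_v.iloc[i],
            "float_value": float_v.iloc[i],
        }
        msg = _validate_row(row, specs_by_id)
        if msg is None:
            keep.append(i)
        else:
            errors.append(RowError(lines[i], msg))

    frame = pd.DataFrame(
        {
            "gtw_id": raw["gtw_id"].astype("string"),
            "obj_id": raw["obj_id"].astype("string"),
            "variable_id": raw["variable_id"].astype("string"),
            "ts": ts,
            "int_value": int_v,
            "float_value": float_v,
            "string_value": raw["string_value"].astype("string"),
            "flags": flags,
        }
    ).iloc[keep]
    return EventLog(frame.reset_index(drop=True), errors)


def write_event_log(log: EventLog, path: str | Path, fmt: str | None = None) -> None:
    """Write an :class:`EventLog` as CSV (default) or JSONL.

    Timestamps are serialised as ISO-8601 UTC so that a read/write
    round-trip is stable up to row order and formatting.
    """
    p = Path(path)
    if fmt is None:
        fmt = "jsonl" if p.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    out = log.frame.copy()
    out["ts"] = out["ts"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str.rstrip("0").str.rstrip(".") + "Z"
    if fmt == "csv":
        out.to_csv(p, index=False)
    elif fmt == "jsonl":
        with open(p, "w") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps({k: v for k, v in rec.items() if not pd.isna(v)},
                                    default=str) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


@dataclass
class SignatureMatrix:
    """Regularly-resampled time x sensor matrix of home state.

    ``data`` is indexed by UTC bin-start timestamps (half-open bins of
    ``bin_width``); columns are sensor ids.  ``kinds`` records each
    sensor's kind, which determines the cell semantics: ON-fraction
    indicator (binary 0/1) for state sensors, activation count for
    impulsive sensors, time-weighted mean for real-valued sensors.
    """

    data: pd.DataFrame
    bin_width: timedelta
    kinds: dict[str, SensorKind]
    binary: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex) or self.data.index.tz is None:
            raise ValueError("SignatureMatrix index must be tz-aware UTC bin starts")
        if self.binary:
            vals = self.data.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binary signature matrix must contain only {0,1}")

    @property
    def sensors(self) -> list[str]:
        return list(self.data.columns)

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index = out.index.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.index.name = "bin_start"
        out.to_csv(path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        kinds: dict[str, SensorKind] | None = None,
        binary: bool = False,
    ) -> "SignatureMatrix":
        data = pd.read_csv(path, index_col=0)
        data.index = pd.to_datetime(data.index, utc=True)
        if len(data) > 1:
            width = data.index[1] - data.index[0]
        else:
            width = timedelta(minutes=1)
        kinds = kinds or {c: "binary_state" for c in data.columns}
        return cls(data=data, bin_width=width, kinds=kinds, binary=binary)


def _bin_floor(ts: pd.Timestamp, origin: pd.Timestamp, width: timedelta) -> int:
    return int((ts - origin) // width)


def _sessions_from_status(ev: pd.DataFrame, log_end: pd.Timestamp) -> list[tuple]:
    """Turn 0/1 status transitions into [(on, off), ...] sessions.

    Overlapping ONs are coalesced with a warning; an ON left open at log
    end is held open to ``log_end`` with a warning.
    """
    sessions: list[tuple] = []
    on_since: pd.Timestamp | None = None
    overlap = False
    for ts_i, v in zip(ev["ts"], ev["int_value"]):
        if v == 1:
            if on_since is None:
                on_since = ts_i
            else:
                overlap = True  # already ON: coalesce
        else:
            if on_since is not None:
                if ts_i > on_since:
                    sessions.append((on_since, ts_i))
                on_since = None
    if on_since is not None:
        warnings.warn("ON without matching OFF at log end; state held open")
        if log_end > on_since:
            sessions.append((on_since, log_end))
    if overlap:
        warnings.warn("overlapping ON events coalesced")
    return sessions


def resample_to_signature(
    events: EventLog,
    specs: Sequence[SensorSpec],
    bin_width: timedelta = timedelta(minutes=1),
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> SignatureMatrix:
    """Convert an event log into a :class:`SignatureMatrix`.

    Parameters
    ----------
    span:
        Optional ``(start, end)`` override of the covered interval, e.g. to
        force full-day coverage; defaults to the event span rounded
        outward to bin boundaries.  Required for an empty log.
    """
    if span is None:
        if len(events) == 0:
            raise ValueError("empty event log requires an explicit span")
        first, last = events.span
    else:
        first, last = span
    origin = pd.Timestamp(first).floor(pd.Timedelta(bin_width))
    end = pd.Timestamp(last)
    n_bins = int(np.ceil((end - origin) / bin_width))
    n_bins = max(n_bins, 1)
    index = pd.date_range(origin, periods=n_bins, freq=pd.Timedelta(bin_width), tz="UTC")
    log_end = origin + n_bins * bin_width

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, SensorKind] = {}
    for spec in specs:
        ev = events.for_sensor(spec.sensor_id, "status") if len(events) else _empty_frame()
        col = np.zeros(n_bins)
        if spec.kind == "binary_state":
            for on, off in _sessions_from_status(ev, log_end):
                i0 = max(_bin_floor(on, origin, bin_width), 0)
                # last bin overlapping the half-open session [on, off)
                i1 = min(int(np.ceil((off - origin) / bin_width)) - 1, n_bins - 1)
                if i1 >= i0:
                    col[i0 : i1 + 1] = 1.0
        elif spec.kind == "impulsive":
            act = ev.loc[ev["int_value"] == 1, "ts"]
            if len(act):
                idx = ((act - origin) // bin_width).astype(int)
                idx = idx[(idx >= 0) & (idx < n_bins)]
                np.add.at(col, idx.to_numpy(), 1.0)
        else:  # real_valued: time-weighted mean of the reported step function
            rep = events.for_sensor(spec.sensor_id, "power") if len(events) else _empty_frame()
            times = list(rep["ts"])
            vals = list(rep["float_value"])
            if times:
                # step function: value holds from each report until the next
                edges = [origin] + times + [log_end]
                levels = [0.0] + vals
                for seg_start, seg_end, level in zip(edges[:-1], edges[1:], levels):
                    if seg_end <= seg_start or level == 0.0:
                        continue
                    i0 = max(_bin_floor(seg_start, origin, bin_width), 0)
                    i1 = min(int(np.ceil((seg_end - origin) / bin_width)) - 1, n_bins - 1)
                    for i in range(i0, i1 + 1):
                        b0 = origin + i * bin_width
                        b1 = b0 + bin_width
                        overlap = (min(seg_end, b1) - max(seg_start, b0)) / bin_width
                        col[i] += level * overlap
        cols[spec.sensor_id] = col
        kinds[spec.sensor_id] = spec.kind

    data = pd.DataFrame(cols, index=index)
    return SignatureMatrix(data=data, bin_width=bin_width, kinds=kinds, binary=False)


def binarize_signature(
    sig: SignatureMatrix, specs: Sequence[SensorSpec]
) -> SignatureMatrix:
    """Reduce a signature matrix to {0,1} activity per bin.

    Binary state columns pass through; impulsive counts become a >=1
    indicator; real-valued columns are thresholded (strictly greater than
    ``binarize_threshold``), so raising the threshold never increases a
    cell.
    """
    specs_by_id = {s.sensor_id: s for s in specs}
    out = {}
    for sensor in sig.sensors:
        spec = specs_by_id[sensor]
        col = sig.data[sensor].to_numpy(dtype=float)
        if spec.kind == "binary_state":
            out[sensor] = (col > 0).astype(float)
        elif spec.kind == "impulsive":
            out[sensor] = (col >= 1).astype(float)
        else:
            if spec.binarize_threshold is None:
                raise ValueError(
                    f"real-valued sensor {sensor!r} needs binarize_threshold"
                )
            out[sensor] = (col > spec.binarize_threshold).astype(float)
    data = pd.DataFrame(out, index=sig.data.index)
    return SignatureMatrix(data=data, bin_width=sig.bin_width, kinds=dict(sig.kinds), binary=True)


@dataclass(frozen=True)
class DailyAggregate:
    """Per-day, per-sensor dashboard numbers: hours active and event count."""

    date: object  # datetime.date in the display timezone
    sensor_id: str
    active_hours: float
    event_count: int
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_hours <= 24.0 + 1e-9):
            raise ValueError("active_hours must be within [0, 24]")
        if self.event_count < 0:
            raise ValueError("event_count must be >= 0")


def daily_aggregate(
    sig: SignatureMatrix,
    events: EventLog,
    specs: Sequence[SensorSpec],
    tz: str | tzinfo = "UTC",
) -> list[DailyAggregate]:
    """Aggregate a signature matrix into per-day activity summaries.

    ``active_hours`` counts active bins x bin width; ``event_count``
    counts distinct OFF->ON transitions (state sensors) or activations
    (impulsive sensors).  Days not fully covered by the matrix are flagged
    ``partial`` so downstream regressions can exclude them.
    """
    bsig = sig if sig.binary else binarize_signature(sig, specs)
    local = bsig.data.copy()
    local.index = local.index.tz_convert(tz)
    dates = local.index.date
    w_hours = sig.bin_width / timedelta(hours=1)
    bins_per_day = int(round(24.0 / w_hours))

    counts: dict[tuple, int] = {}
    for spec in specs:
        ev = events.for_sensor(spec.sensor_id, "status")
        if spec.kind == "binary_state":
            ons = ev.loc[ev["int_value"] == 1, "ts"]
        else:
            ons = ev.loc[ev["int_value"] == 1, "ts"]
        for ts in ons:
            d = ts.tz_convert(tz).date()
            counts[(d, spec.sensor_id)] = counts.get((d, spec.sensor_id), 0) + 1

    out: list[DailyAggregate] = []
    for d, group in local.groupby(dates):
        partial = len(group) < bins_per_day
        for sensor in bsig.sensors:
            out.append(
                DailyAggregate(
                    date=d,
                    sensor_id=sensor,
                    active_hours=float(group[sensor].sum() * w_hours),
                    event_count=int(counts.get((d, sensor), 0)),
                    partial=partial,
                )
            )
    return out
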