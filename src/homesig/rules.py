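"""Pilot-management rules replayed over an event log.

Desk-scale equivalent of the hot-path monitoring rules: low battery,
missing keep-alives and grossly abnormal prolonged states (e.g. a front
door left open).  Evaluation is batch replay over a log — behaviourally
identical to stream evaluation at this scale — and alerts are deduplicated
per ongoing condition, so one stuck door yields one alert.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Sequence

import pandas as pd

from .events import EventLog, SensorSpec, _sessions_from_status

__all__ = ["RuleSpec", "Alert", "run_rules"]


@dataclass(frozen=True)
class RuleSpec:
    """One monitoring rule.

    ``threshold`` is a battery percentage (low_battery), a multiple of the
    sensor's keep-alive interval (keepalive_gap), or a maximum ON duration
    in minutes (prolonged_state).  All comparisons are strict.
    """

    rule_id: str
    sensor_id: str
    kind: str  # low_battery | keepalive_gap | prolonged_state
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("low_battery", "keepalive_gap", "prolonged_state"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("rule threshold must be > 0")


@dataclass(frozen=True)
class Alert:
    rule_id: str
    sensor_id: str
    trigger_time: pd.Timestamp
    detail: str


def run_rules(
    events: EventLog,
    rules: Sequence[RuleSpec],
    specs: Sequence[SensorSpec],
    now: pd.Timestamp,
) -> list[Alert]:
    """Evaluate rules over a log as of ``now`` and return deduplicated alerts."""
    specs_by_id = {s.sensor_id: s for s in specs}
    for rule in rules:
        if rule.sensor_id not in specs_by_id:
            raise ValueError(f"rule {rule.rule_id!r} references unknown sensor {rule.sensor_id!r}")
    now = pd.Timestamp(now)
    alerts: list[Alert] = []
    for rule in rules:
        spec = specs_by_id[rule.sensor_id]
        if rule.kind == "low_battery":
            batt = events.for_sensor(rule.sensor_id, "battery")
            if len(batt) == 0:
                continue
            last = batt.iloc[-1]
            level = last["float_value"] if pd.notna(last["float_value"]) else last["int_value"]
            if level is not None and float(level) < rule.threshold:
                alerts.append(
                    Alert(rule.rule_id, rule.sensor_id, last["ts"],
                          f"battery at {float(level):.1f}% < {rule.threshold:g}%")
                )
        elif rule.kind == "keepalive_gap":
            ev = events.for_sensor(rule.sensor_id)
            if len(ev) == 0:
                continue
            last_ts = ev["ts"].iloc[-1]
            limit = rule.threshold * spec.keepalive_interval
            if (now - last_ts) > limit:
                alerts.append(
                    Alert(rule.rule_id, rule.sensor_id, last_ts + limit,
                          f"silent for {(now - last_ts) / timedelta(minutes=1):.0f} min "
                          f"(> {limit / timedelta(minutes=1):.0f} min)")
                )
        else:  # prolonged_state
            ev = events.for_sensor(rule.sensor_id, "status")
            max_dur = timedelta(minutes=rule.threshold)
            for on, off in _sessions_from_status(ev, now):
                if (off - on) > max_dur:
                    alerts.append(
                        Alert(rule.rule_id, rule.sensor_id, on + max_dur,
                              f"ON for {(off - on) / timedelta(minutes=1):.0f} min "
                              f"(> {rule.threshold:g} min)")
                    )
    return alerts
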