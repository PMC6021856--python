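"""Shared fixtures: tiny hand-written event logs and sensor specs."""

from datetime import timedelta

import pandas as pd
import pytest

from homesig.events import EventLog, SensorSpec


def make_log(rows):
    """Build an EventLog from (sensor, variable, ts, int_value, float_value) tuples."""
    frame = pd.DataFrame(
        {
            "gtw_id": pd.Series(["gw"] * len(rows), dtype="string"),
            "obj_id": pd.Series([r[0] for r in rows], dtype="string"),
            "variable_id": pd.Series([r[1] for r in rows], dtype="string"),
            "ts": pd.to_datetime([r[2] for r in rows], utc=True),
            "int_value": pd.Series([r[3] for r in rows], dtype="Int64"),
            "float_value": pd.Series(
                [r[4] if len(r) > 4 else None for r in rows], dtype="float64"
            ),
            "string_value": pd.Series([None] * len(rows), dtype="string"),
            "flags": pd.Series([None] * len(rows), dtype="Int64"),
        }
    )
    return EventLog(frame)


@pytest.fixture
def bed_spec():
    return SensorSpec(sensor_id="bed", kind="binary_state")


@pytest.fixture
def toilet_spec():
    return SensorSpec(sensor_id="toilet", kind="impulsive")


@pytest.fixture
def tv_spec():
    return SensorSpec(
        sensor_id="tv", kind="real_valued", binarize_threshold=50.0,
        keepalive_interval=timedelta(minutes=60),
    )
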