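"""Shared fixtures: small synthetic objects built fresh per test."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from dialact.raw_io import ParticipantRecord, RawTrace
from dialact.synthetic import BehaviourSchedule, GeneratorConfig
from dialact.wear_qc import MinuteGrid


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A desk-scale cohort for tests that iterate."""
    return GeneratorConfig(n_participants=8, wear_days=4, seed=42)


@pytest.fixture
def participant() -> ParticipantRecord:
    return ParticipantRecord(
        id="P001",
        age=66.0,
        sex="male",
        dialysis_weekdays=(0, 2, 4),
        slot="morning",
        leg_weakness=True,
        wear_season="winter",
    )


@pytest.fixture
def control() -> ParticipantRecord:
    return ParticipantRecord(id="C001", age=64.0, sex="female", wear_season="summer")


def make_trace(xyz: np.ndarray, rate_hz: float = 25.0, start: str = "2016-11-07") -> RawTrace:
    n = len(xyz)
    t = np.datetime64(f"{start}T00:00:00", "ns") + (
        np.arange(n) * int(1e9 / rate_hz)
    ).astype("timedelta64[ns]")
    import pandas as pd

    return RawTrace(
        device_id="TEST",
        sample_rate_hz=rate_hz,
        start_time=pd.Timestamp(f"{start}T00:00:00"),
        t=t,
        xyz=np.asarray(xyz, dtype=float),
    )


def single_state_schedule(state: str, day: dt.date = dt.date(2016, 11, 8)) -> BehaviourSchedule:
    return BehaviourSchedule(day=day, day_type="non-dialysis", segments=[(0.0, 24.0, state)])


def make_grid(
    n_days: int = 3,
    day_types: list[str] | None = None,
    vm_value: float = 10.0,
    state_value: str = "sedentary",
    participant_id: str = "P001",
) -> MinuteGrid:
    """Fully worn constant grid; callers then poke holes as needed."""
    if day_types is None:
        day_types = ["dialysis" if i % 2 == 0 else "non-dialysis" for i in range(n_days)]
    days = [(dt.date(2016, 11, 7) + dt.timedelta(days=i), ty) for i, ty in enumerate(day_types)]
    return MinuteGrid(
        participant_id=participant_id,
        days=days,
        vm=np.full((n_days, 1440), float(vm_value)),
        state=np.full((n_days, 1440), state_value, dtype=object),
        wear=np.ones((n_days, 1440), dtype=bool),
        imputed=np.zeros((n_days, 1440), dtype=bool),
    )
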