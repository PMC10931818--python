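"""Shared fixtures: small synthetic sessions and configs for fast unit tests."""

import numpy as np
import pytest

from danseq.behavior import EventLog
from danseq.simulate import SimulationConfig


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """A cohort small enough for sub-second simulation in unit tests."""
    return SimulationConfig(
        n_mice=2,
        n_neurons_total=10,
        session_duration=300.0,
        n_lesion_mice=3,
        n_saline_mice=3,
    )


@pytest.fixture
def simple_log() -> EventLog:
    """Two bouts (3 and 4 presses, second rewarded) plus one orphan press."""
    return EventLog(
        session_id="s1",
        mouse_id="m1",
        day_index=0,
        lever_side="left",
        hemisphere="right",
        press_times=np.array([10.0, 10.3, 10.6, 40.0, 40.3, 40.6, 40.9, 70.0]),
        lick_times=np.array([43.0]),
        reward_times=np.array([40.9]),
        occupancy_intervals=np.array([[9.5, 11.0], [39.5, 41.5]]),
        session_duration=120.0,
    )
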