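"""Sequence segmentation, reward rule, and session metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from danseq.behavior import (
    EventLog,
    LENGTH_GROUPS,
    SequenceBout,
    assign_length_group,
    behavior_metrics,
    bouts_to_frame,
    length_group_rank,
    read_event_log,
    reward_eligible,
    segment_sequences,
    target_ipi,
)


# ---------------------------------------------------------------------------
# reward rule


def test_target_ipi():
    assert target_ipi(4, 1.0) == pytest.approx(1.0 / 3.0)
    assert target_ipi(2, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        target_ipi(1)


def test_reward_eligible_strict_window():
    fast = SequenceBout(np.array([0.0, 0.3, 0.6, 0.9]))
    exact = SequenceBout(np.array([0.0, 0.34, 0.67, 1.0]))
    assert reward_eligible(fast, 4, 1.0)
    assert not reward_eligible(exact, 4, 1.0)  # span == window fails the strict rule
    assert not reward_eligible(SequenceBout(np.array([0.0, 0.3, 0.6])), 4, 1.0)
    # a late fast run inside a longer bout still qualifies
    late = SequenceBout(np.array([0.0, 3.0, 3.2, 3.4, 3.6]))
    assert reward_eligible(late, 4, 1.0)
    with pytest.raises(ValueError):
        reward_eligible(fast, 1, 1.0)


# ---------------------------------------------------------------------------
# length groups


def test_length_groups_and_ranks():
    assert assign_length_group(1) == "<=2"
    assert assign_length_group(2) == "<=2"
    assert assign_length_group(4) == "4"
    assert assign_length_group(7) == "7+"
    assert assign_length_group(30) == "7+"
    assert [length_group_rank(g) for g in LENGTH_GROUPS] == [1, 2, 3, 4, 5, 6]
    with pytest.raises(ValueError):
        assign_length_group(0)


# ---------------------------------------------------------------------------
# segmentation


def test_segment_by_occupancy(simple_log):
    bouts = segment_sequences(simple_log)
    assert [b.n_presses for b in bouts] == [3, 4]
    assert [b.rewarded for b in bouts] == [False, True]
    assert all(b.limb == "contra" for b in bouts)  # left lever, right hemisphere
    assert sum(b.n_presses for b in bouts) == simple_log.press_times.size - 1  # one orphan


def test_segment_by_gap_rule():
    log = EventLog(
        session_id="s",
        mouse_id="m",
        day_index=0,
        lever_side="left",
        press_times=np.array([0.0, 0.5, 1.0, 5.0, 5.2]),
        session_duration=10.0,
    )
    bouts = segment_sequences(log, gap_threshold=2.0)
    assert [b.n_presses for b in bouts] == [3, 2]


def test_segment_empty():
    log = EventLog("s", "m", 0, "left", session_duration=10.0)
    assert segment_sequences(log) == []


@settings(deadline=None, max_examples=30)
@given(
    gaps=st.lists(
        st.one_of(st.floats(0.05, 1.8), st.floats(2.2, 10.0)),  # stay off the gate
        min_size=1, max_size=30,
    ),
    shift=st.floats(0.0, 50.0),
)
def test_segmentation_properties(gaps, shift):
    """Press conservation and time-shift invariance of the gap rule."""
    press = np.cumsum(np.asarray(gaps))
    log = EventLog("s", "m", 0, "left", press_times=press,
                   session_duration=float(press[-1]) + 1.0)
    bouts = segment_sequences(log, gap_threshold=2.0)
    assert sum(b.n_presses for b in bouts) == press.size  # no press lost
    shifted = EventLog("s", "m", 0, "left", press_times=press + shift,
                       session_duration=float(press[-1]) + shift + 1.0)
    bouts2 = segment_sequences(shifted, gap_threshold=2.0)
    assert [b.n_presses for b in bouts2] == [b.n_presses for b in bouts]


# ---------------------------------------------------------------------------
# event-log validation


def test_eventlog_validation():
    with pytest.raises(ValueError):
        EventLog("s", "m", 0, "left", press_times=[1.0, 1.0], session_duration=5.0)
    with pytest.raises(ValueError):
        EventLog("s", "m", 0, "left", press_times=[1.0, 9.0], session_duration=5.0)
    with pytest.raises(ValueError):
        EventLog("s", "m", 0, "left", occupancy_intervals=[[1.0, 0.5]], session_duration=5.0)
    with pytest.raises(ValueError):
        EventLog("s", "m", 0, "left", occupancy_intervals=[[0.0, 2.0], [1.0, 3.0]],
                 session_duration=5.0)


def test_limb_mapping():
    log = EventLog("s", "m", 0, "left", hemisphere="right", session_duration=1.0)
    assert log.limb == "contra"
    assert EventLog("s", "m", 0, "left", hemisphere="left", session_duration=1.0).limb == "ipsi"
    assert EventLog("s", "m", 0, "left", session_duration=1.0).limb == "none"


# ---------------------------------------------------------------------------
# metrics


def test_behavior_metrics_values(simple_log):
    bouts = segment_sequences(simple_log)
    m = behavior_metrics(simple_log, bouts)
    assert m.total_presses == 8
    assert m.n_orphan_presses == 1
    assert m.pct_bouts_multi_press == 100.0
    assert m.mean_presses_per_sequence == pytest.approx(3.5)
    # within-bout IPIs are all 0.3 s
    assert m.ipi_mean == pytest.approx(0.3)


def test_ipi_fano_known_value():
    log = EventLog("s", "m", 0, "left",
                   press_times=np.array([0.0, 0.2, 0.6]), session_duration=5.0)
    m = behavior_metrics(log, segment_sequences(log, gap_threshold=2.0))
    # IPIs [0.2, 0.4]: sample var 0.02, mean 0.3 -> Fano 0.0667
    assert m.ipi_fano == pytest.approx(0.02 / 0.3)


def test_bouts_to_frame(simple_log):
    df = bouts_to_frame(segment_sequences(simple_log))
    assert list(df.columns) == ["session_id", "start", "end", "n_presses",
                                "length_group", "rewarded", "limb"]
    assert df.n_presses.tolist() == [3, 4]
    assert df.length_group.tolist() == ["3", "4"]


# ---------------------------------------------------------------------------
# reading


def test_read_event_log_roundtrip(tmp_path):
    events = pd.DataFrame(
        {
            "time": [9.5, 10.0, 10.3, 10.6, 11.5, 10.9, 13.0],
            "event_type": ["roi_enter", "press", "press", "press", "roi_exit",
                           "reward", "lick"],
        }
    )
    path = tmp_path / "events.csv"
    events.to_csv(path, index=False)
    row = {"session_id": "s1", "mouse_id": "m1", "day_index": 0,
           "lever_side": "left", "hemisphere": "right", "epoch": "none",
           "treatment": "none", "session_duration": 20.0}
    log = read_event_log(path, row)
    assert log.press_times.size == 3
    assert log.occupancy_intervals.shape == (1, 2)
    assert log.limb == "contra"
    bouts = segment_sequences(log)
    assert len(bouts) == 1 and bouts[0].rewarded


def test_read_event_log_errors(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"time": [1.0], "event_type": ["jump"]}).to_csv(path, index=False)
    row = {"session_id": "s", "mouse_id": "m", "day_index": 0, "lever_side": "left",
           "hemisphere": "none", "epoch": "none", "treatment": "none",
           "session_duration": 5.0}
    with pytest.raises(ValueError):
        read_event_log(path, row)
    pd.DataFrame({"time": [1.0], "event_type": ["roi_enter"]}).to_csv(path, index=False)
    with pytest.raises(ValueError):
        read_event_log(path, row)  # unpaired occupancy
    pd.DataFrame({"t": [1.0]}).to_csv(path, index=False)
    with pytest.raises(ValueError):
        read_event_log(path, row)
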