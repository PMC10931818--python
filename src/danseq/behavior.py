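"""Lever-press behavior: event logs, sequence segmentation, session metrics.

A movement sequence ("bout") is a maximal run of lever presses performed
while the animal's snout occupies a spatial region of interest next to the
lever.  A bout can contain a single press; presses falling outside any
occupancy interval are orphans — flagged, excluded from bouts, and counted.
For logs without position data an inter-press-gap rule is available
(a gap larger than a threshold splits bouts).

Under the task's fixed-ratio rule, ``n_required`` presses inside a
``window``-second span earn a reward, which puts the target inter-press
interval at window/(n_required-1) — 0.333 s for 4 presses in 1 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("danseq")

LENGTH_GROUPS = ("<=2", "3", "4", "5", "6", "7+")

__all__ = [
    "EventLog",
    "SequenceBout",
    "BehaviorMetrics",
    "LENGTH_GROUPS",
    "read_event_log",
    "segment_sequences",
    "assign_length_group",
    "length_group_rank",
    "reward_eligible",
    "target_ipi",
    "behavior_metrics",
    "bouts_to_frame",
]


@dataclass
class EventLog:
    """One session's behavioral timestamps plus metadata (seconds, 0-based)."""

    session_id: str
    mouse_id: str
    day_index: int
    lever_side: str                       # {"left", "right"}
    hemisphere: str = "none"              # imaged or lesioned: {"left","right","none"}
    epoch: str = "none"                   # {"before", "after", "none"}
    treatment: str = "none"               # {"6OHDA", "saline", "none"}
    press_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    occupancy_intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    press_velocity: np.ndarray | None = None
    session_duration: float = 0.0

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        self.reward_times = np.asarray(self.reward_times, dtype=float)
        occ = np.asarray(self.occupancy_intervals, dtype=float).reshape(-1, 2)
        self.occupancy_intervals = occ
        if self.press_times.size and np.any(np.diff(self.press_times) <= 0):
            raise ValueError(f"{self.session_id}: press times not strictly increasing")
        for name, t in (("press", self.press_times), ("lick", self.lick_times),
                        ("reward", self.reward_times)):
            if t.size and (t.min() < 0 or t.max() > self.session_duration):
                raise ValueError(f"{self.session_id}: {name} time outside session")
        if occ.size:
            if np.any(occ[:, 1] <= occ[:, 0]):
                raise ValueError(f"{self.session_id}: degenerate occupancy interval")
            order = np.argsort(occ[:, 0])
            occ = occ[order]
            if np.any(occ[1:, 0] < occ[:-1, 1]):
                raise ValueError(f"{self.session_id}: overlapping occupancy intervals")
            self.occupancy_intervals = occ

    @property
    def limb(self) -> str:
        """'contra' if the lever side is opposite the imaged/lesioned hemisphere."""
        if self.hemisphere == "none":
            return "none"
        return "contra" if self.lever_side != self.hemisphere else "ipsi"


@dataclass
class SequenceBout:
    press_times: np.ndarray
    rewarded: bool = False
    limb: str = "none"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        if self.press_times.size == 0:
            raise ValueError("empty bout")

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)

    @property
    def start(self) -> float:
        return float(self.press_times[0])

    @property
    def end(self) -> float:
        return float(self.press_times[-1])

    @property
    def ipis(self) -> np.ndarray:
        return np.diff(self.press_times)

    @property
    def length_group(self) -> str:
        return assign_length_group(self.n_presses)


@dataclass
class BehaviorMetrics:
    total_presses: int
    presses_per_min: float
    pct_presses_in_sequence: float
    pct_bouts_multi_press: float
    mean_presses_per_sequence: float
    ipi_mean: float
    ipi_fano: float
    n_orphan_presses: int
    mean_press_velocity: float | None = None


# ---------------------------------------------------------------------------
# reading


_MANIFEST_COLUMNS = ["session_id", "mouse_id", "day_index", "lever_side",
                     "hemisphere", "epoch", "treatment", "session_duration"]
_EVENT_TYPES = {"press", "lick", "reward", "roi_enter", "roi_exit"}


def read_event_log(events_path, manifest_row) -> EventLog:
    """Build an :class:`EventLog` from a long-format events file.

    The events file has columns ``time, event_type[, velocity]`` with
    event_type in {press, lick, reward, roi_enter, roi_exit}; the manifest
    row (mapping or Series) carries the session metadata.
    """
    df = pd.read_csv(events_path, sep=None, engine="python")
    missing = {"time", "event_type"} - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    bad = set(df["event_type"].unique()) - _EVENT_TYPES
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    meta = dict(manifest_row)
    for c in _MANIFEST_COLUMNS:
        if c not in meta:
            raise ValueError(f"manifest missing column {c!r}")

    t = df.sort_values("time")
    press = t.loc[t.event_type == "press", "time"].to_numpy(float)
    lick = t.loc[t.event_type == "lick", "time"].to_numpy(float)
    reward = t.loc[t.event_type == "reward", "time"].to_numpy(float)
    enters = t.loc[t.event_type == "roi_enter", "time"].to_numpy(float)
    exits = t.loc[t.event_type == "roi_exit", "time"].to_numpy(float)
    if enters.size != exits.size:
        raise ValueError("unpaired roi_enter/roi_exit events")
    occ = np.column_stack([enters, exits]) if enters.size else np.empty((0, 2))

    vel = None
    if "velocity" in t.columns:
        v = t.loc[t.event_type == "press", "velocity"].to_numpy(float)
        if np.isfinite(v).all():
            vel = v
    return EventLog(
        session_id=str(meta["session_id"]),
        mouse_id=str(meta["mouse_id"]),
        day_index=int(meta["day_index"]),
        lever_side=str(meta["lever_side"]),
        hemisphere=str(meta["hemisphere"]),
        epoch=str(meta["epoch"]),
        treatment=str(meta["treatment"]),
        press_times=press,
        lick_times=lick,
        reward_times=reward,
        occupancy_intervals=occ,
        press_velocity=vel,
        session_duration=float(meta["session_duration"]),
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_sequences(log: EventLog, gap_threshold: float = 2.0) -> list[SequenceBout]:
    """Segment presses into bouts.

    With occupancy intervals present, a bout is the maximal run of presses
    sharing one snout-in-ROI interval; presses in no interval are orphans.
    Without position data, a press starts a new bout whenever the gap from
    the previous press exceeds ``gap_threshold`` seconds.
    """
    press = log.press_times
    if press.size == 0:
        return []
    bouts: list[SequenceBout] = []
    if log.occupancy_intervals.size:
        occ = log.occupancy_intervals
        idx = np.searchsorted(occ[:, 0], press, side="right") - 1
        inside = (idx >= 0) & (press < occ[np.clip(idx, 0, None), 1])
        n_orphans = int((~inside).sum())
        if n_orphans:
            logger.info("%s: %d orphan presses outside occupancy", log.session_id, n_orphans)
        for interval in np.unique(idx[inside]):
            sel = inside & (idx == interval)
            bouts.append(SequenceBout(press[sel], limb=log.limb, session_id=log.session_id))
    else:
        splits = np.flatnonzero(np.diff(press) > gap_threshold) + 1
        for chunk in np.split(press, splits):
            bouts.append(SequenceBout(chunk, limb=log.limb, session_id=log.session_id))
    # reward flag: a reward event during or within 1 s after the bout span
    for b in bouts:
        if log.reward_times.size:
            b.rewarded = bool(
                np.any((log.reward_times >= b.start) & (log.reward_times <= b.end + 1.0))
            )
    return bouts


def orphan_presses(log: EventLog, bouts: list[SequenceBout]) -> int:
    in_bouts = sum(b.n_presses for b in bouts)
    return int(log.press_times.size - in_bouts)


def assign_length_group(n_presses: int) -> str:
    """Grouped sequence lengths: 1-2 pooled, 3..6 singletons, 7+ pooled."""
    n = int(n_presses)
    if n < 1:
        raise ValueError("a bout has at least one press")
    if n <= 2:
        return "<=2"
    if n >= 7:
        return "7+"
    return str(n)


def length_group_rank(group: str) -> int:
    """Ordinal rank of a length group (1-based), for rank correlations."""
    return LENGTH_GROUPS.index(group) + 1


def reward_eligible(bout: SequenceBout, n_required: int = 4, window: float = 1.0) -> bool:
    """True iff some ``n_required`` consecutive presses span less than ``window`` s."""
    if n_required < 2 or window <= 0:
        raise ValueError("need n_required >= 2 and window > 0")
    t = bout.press_times
    if t.size < n_required:
        return False
    spans = t[n_required - 1:] - t[: t.size - n_required + 1]
    return bool(np.any(spans < window))


def target_ipi(n_presses: int = 4, window: float = 1.0) -> float:
    """Inter-press interval implied by the reward rule: window/(n-1)."""
    if n_presses < 2:
        raise ValueError("target IPI needs >= 2 presses")
    return window / (n_presses - 1)


# ---------------------------------------------------------------------------
# session metrics


def behavior_metrics(log: EventLog, bouts: list[SequenceBout]) -> BehaviorMetrics:
    """Fig-1-style session summaries; IPIs are within-bout only."""
    total = int(log.press_times.size)
    in_bouts = sum(b.n_presses for b in bouts)
    in_seq = sum(b.n_presses for b in bouts if b.n_presses >= 2)
    ipis = np.concatenate([b.ipis for b in bouts]) if bouts else np.empty(0)
    dur_min = log.session_duration / 60.0 if log.session_duration > 0 else np.nan
    if ipis.size >= 2 and ipis.mean() > 0:
        fano = float(np.var(ipis, ddof=1) / ipis.mean())
    else:
        fano = float("nan")
    vel = None
    if log.press_velocity is not None and log.press_velocity.size:
        vel = float(np.mean(log.press_velocity))
    return BehaviorMetrics(
        total_presses=total,
        presses_per_min=total / dur_min if dur_min else float("nan"),
        pct_presses_in_sequence=100.0 * in_seq / total if total else float("nan"),
        pct_bouts_multi_press=(
            100.0 * sum(b.n_presses >= 2 for b in bouts) / len(bouts) if bouts else float("nan")
        ),
        mean_presses_per_sequence=(
            float(np.mean([b.n_presses for b in bouts])) if bouts else float("nan")
        ),
        ipi_mean=float(ipis.mean()) if ipis.size else float("nan"),
        ipi_fano=fano,
        n_orphan_presses=total - in_bouts,
        mean_press_velocity=vel,
    )


def bouts_to_frame(bouts: list[SequenceBout]) -> pd.DataFrame:
    """Tidy bouts table (one row per bout) for export and downstream joins."""
    return pd.DataFrame(
        {
            "session_id": [b.session_id for b in bouts],
            "start": [b.start for b in bouts],
            "end": [b.end for b in bouts],
            "n_presses": [b.n_presses for b in bouts],
            "length_group": [b.length_group for b in bouts],
            "rewarded": [b.rewarded for b in bouts],
            "limb": [b.limb for b in bouts],
        }
    )
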