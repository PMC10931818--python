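"""Calcium-trace processing: normalization, PETHs, and modulation classes.

Traces are z-scored per neuron per session, then aligned on behavioral
events into peri-event time histograms (PETHs) spanning -8 to +6 s in
0.1-s bins.  Bins from -8 to -3 s form the baseline distribution; a neuron
is positively modulated in a test window when at least two consecutive
bins of its mean PETH exceed the 99th percentile of the baseline bins
(negative modulation symmetrically with the 1st percentile).

Classes, from the press- and lick-aligned PETHs of one neuron/condition:

* movement_initiation — modulated in the 2 s before the first press;
* execution           — modulated between first press and sequence end
                        (fixed 0..+1 s fallback) but not before the press;
* reward              — modulated 0..1 s after the first rewarded lick and
                        not in the 2 s before it;
* magazine_approach   — modulated in the 2 s before the rewarded lick
                        (ramping during approach to the reward magazine).

Peak activity is the maximum of a centered 3-bin moving average inside a
window (2 s pre-press for lateralization contrasts, 1 s for matched-session
length analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "PethSet",
    "zscore_traces",
    "build_peth",
    "classify_modulation",
    "modulation_mask",
    "classify_neuron",
    "max_activity",
    "read_traces_h5",
    "write_traces_h5",
]

PETH_WINDOW = (-8.0, 6.0)
BASELINE_WINDOW = (-8.0, -3.0)
BIN_WIDTH = 0.1
PRE_PRESS_WINDOW = (-2.0, 0.0)
POST_LICK_WINDOW = (0.0, 1.0)
EXECUTION_WINDOW = (0.0, 1.0)


@dataclass
class TraceMatrix:
    """Per-session fluorescence: neurons x samples at a fixed sampling rate."""

    session_id: str
    neuron_ids: list[str]
    values: np.ndarray
    sampling_rate: float = 10.0
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.neuron_ids):
            raise ValueError("values must be (n_neurons, n_samples)")
        if not np.isfinite(self.values).all():
            raise ValueError("traces contain non-finite samples")

    @property
    def duration(self) -> float:
        return self.values.shape[1] / self.sampling_rate


@dataclass
class PethSet:
    """Trial-aligned matrices and mean PETH for one neuron/event/condition."""

    neuron_id: str
    event_type: str                      # {"first_press", "rewarded_lick"}
    condition: str                       # {"contra", "ipsi"} or "none"
    bin_edges: np.ndarray                # n_bins + 1 edges, seconds from event
    trial_matrix: np.ndarray             # trials x bins
    n_dropped_trials: int = 0
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    event_mask: np.ndarray | None = None  # which input events produced trials

    @property
    def mean_peth(self) -> np.ndarray:
        return self.trial_matrix.mean(axis=0)

    @property
    def n_trials(self) -> int:
        return self.trial_matrix.shape[0]

    def window_slice(self, window: tuple[float, float]) -> slice:
        return _window_slice(self.bin_edges, window)


def _window_slice(edges: np.ndarray, window: tuple[float, float]) -> slice:
    lo, hi = window
    left = edges[:-1]
    if lo < edges[0] - 1e-9 or hi > edges[-1] + 1e-9:
        raise ValueError(f"window {window} outside PETH span ({edges[0]}, {edges[-1]})")
    i0 = int(np.searchsorted(left, lo - 1e-9))
    i1 = int(np.searchsorted(left, hi - 1e-9))
    return slice(i0, i1)


# ---------------------------------------------------------------------------
# normalization


def zscore_traces(t: TraceMatrix) -> TraceMatrix:
    """Per-neuron, per-session standardization (population sd).

    Zero-variance rows are left at 0.  Idempotent on already-normalized
    input up to floating error; refuses a matrix flagged z-scored.
    """
    if t.zscored:
        raise ValueError("traces already z-scored")
    mu = t.values.mean(axis=1, keepdims=True)
    sd = t.values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (t.values - mu) / sd
    z[flat] = 0.0
    return TraceMatrix(t.session_id, list(t.neuron_ids), z, t.sampling_rate, zscored=True)


# ---------------------------------------------------------------------------
# PETH construction


def build_peth(
    t: TraceMatrix,
    events,
    neuron: int | str = 0,
    event_type: str = "first_press",
    condition: str = "none",
    window: tuple[float, float] = PETH_WINDOW,
    bin_width: float = BIN_WIDTH,
) -> PethSet:
    """Align one neuron's trace on events; bins are left-closed [t0, t0+bin).

    Events whose full window falls outside the recording are dropped and
    counted in ``n_dropped_trials``.
    """
    if not t.zscored:
        raise ValueError("build_peth expects z-scored traces")
    if isinstance(neuron, str):
        neuron = t.neuron_ids.index(neuron)
    row = t.values[neuron]
    fs = t.sampling_rate
    per_bin = bin_width * fs
    m = int(round(per_bin))
    if m < 1 or abs(per_bin - m) > 1e-9:
        raise ValueError("bin width must be an integer number of samples")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)

    events = np.asarray(events, dtype=float)
    start = np.round((events + window[0]) * fs).astype(int)
    ok = (start >= 0) & (start + n_bins * m <= row.size)
    dropped = int((~ok).sum())
    idx = start[ok][:, None] + np.arange(n_bins * m)[None, :]
    trials = row[idx].reshape(-1, n_bins, m).mean(axis=2) if ok.any() else np.empty((0, n_bins))
    return PethSet(
        neuron_id=str(t.neuron_ids[neuron]),
        event_type=event_type,
        condition=condition,
        bin_edges=edges,
        trial_matrix=trials,
        n_dropped_trials=dropped,
        event_mask=ok,
    )


def build_peths_all(
    t: TraceMatrix,
    events,
    event_type: str = "first_press",
    condition: str = "none",
    window: tuple[float, float] = PETH_WINDOW,
    bin_width: float = BIN_WIDTH,
) -> list[PethSet]:
    """One PethSet per neuron, sharing the trial alignment."""
    return [
        build_peth(t, events, i, event_type, condition, window, bin_width)
        for i in range(len(t.neuron_ids))
    ]


# ---------------------------------------------------------------------------
# modulation test


def modulation_mask(
    peths: np.ndarray,
    baseline: slice,
    test: slice,
    percentile: float = 99.0,
    min_consecutive: int = 2,
    direction: str = "positive",
) -> np.ndarray:
    """Vectorized consecutive-bin percentile rule over rows of mean PETHs.

    Returns a boolean per row: does the test window contain at least
    ``min_consecutive`` consecutive bins beyond the given percentile of that
    row's baseline bins?
    """
    p = np.atleast_2d(np.asarray(peths, dtype=float))
    base = p[:, baseline]
    if direction == "positive":
        thr = np.percentile(base, percentile, axis=1, keepdims=True)
        exceed = p[:, test] > thr
    else:
        thr = np.percentile(base, 100.0 - percentile, axis=1, keepdims=True)
        exceed = p[:, test] < thr
    if exceed.shape[1] < min_consecutive:
        return np.zeros(p.shape[0], dtype=bool)
    run = np.ones_like(exceed[:, : exceed.shape[1] - min_consecutive + 1])
    for k in range(min_consecutive):
        run &= exceed[:, k : k + run.shape[1]]
    return run.any(axis=1)


def classify_modulation(
    p: PethSet,
    test_window: tuple[float, float],
    min_consecutive: int = 2,
    percentile: float = 99.0,
) -> tuple[bool, str, int | None]:
    """Apply the consecutive-bin percentile rule to one mean PETH.

    Returns (is_modulated, direction, onset_bin); direction is 'positive'
    when the 99th-percentile exceedance fires, 'negative' for the symmetric
    1st-percentile rule, 'none' otherwise.  A constant baseline makes the
    threshold equal that constant (degenerate but well-defined).
    """
    base_sl = p.window_slice(p.baseline_window)
    test_sl = p.window_slice(test_window)
    mean = p.mean_peth
    base = mean[base_sl]
    for direction, thr, cmp in (
        ("positive", np.percentile(base, percentile), np.greater),
        ("negative", np.percentile(base, 100.0 - percentile), np.less),
    ):
        exceed = cmp(mean[test_sl], thr)
        run = 0
        for i, e in enumerate(exceed):
            run = run + 1 if e else 0
            if run >= min_consecutive:
                return True, direction, test_sl.start + i - min_consecutive + 1
    return False, "none", None


# ---------------------------------------------------------------------------
# neuron classes


def classify_neuron(
    p_press: PethSet | None,
    p_lick: PethSet | None,
    pre_window: tuple[float, float] = PRE_PRESS_WINDOW,
    post_lick_window: tuple[float, float] = POST_LICK_WINDOW,
    execution_window: tuple[float, float] = EXECUTION_WINDOW,
    percentile: float = 99.0,
    min_consecutive: int = 2,
) -> dict:
    """One ModulationTable row for a neuron/condition pair of PETHs."""
    row = {
        "neuron_id": None,
        "condition": None,
        "movement": False,
        "execution": False,
        "reward": False,
        "magazine_approach": False,
        "class": "none",
        "max_pre_press": np.nan,
        "flagged_missing": False,
    }
    if p_press is not None and p_press.n_trials > 0:
        row["neuron_id"] = p_press.neuron_id
        row["condition"] = p_press.condition
        mov, d, _ = classify_modulation(p_press, pre_window, min_consecutive, percentile)
        mov = mov and d == "positive"
        exe, d, _ = classify_modulation(p_press, execution_window, min_consecutive, percentile)
        row["movement"] = mov
        row["execution"] = bool(exe and d == "positive" and not mov)
        row["max_pre_press"] = max_activity(p_press, pre_window)
    else:
        row["flagged_missing"] = True
    if p_lick is not None and p_lick.n_trials > 0:
        row["neuron_id"] = row["neuron_id"] or p_lick.neuron_id
        row["condition"] = row["condition"] or p_lick.condition
        post, d1, _ = classify_modulation(p_lick, post_lick_window, min_consecutive, percentile)
        pre, d2, _ = classify_modulation(p_lick, pre_window, min_consecutive, percentile)
        mag = bool(pre and d2 == "positive")
        row["magazine_approach"] = mag
        row["reward"] = bool(post and d1 == "positive" and not mag)
        row["max_post_lick"] = max_activity(p_lick, post_lick_window)
        row["max_pre_lick"] = max_activity(p_lick, pre_window)
    else:
        row["flagged_missing"] = True
    for cls in ("movement", "reward", "magazine_approach", "execution"):
        if row.get(cls):
            row["class"] = "movement_initiation" if cls == "movement" else cls
            break
    return row


def max_activity(
    p: PethSet, window: tuple[float, float], smooth_bins: int = 3
) -> float:
    """Peak of the centered ``smooth_bins``-bin moving average in a window.

    The moving window truncates at the window's edges (2-bin means there),
    so the boundary bins still contribute candidates.
    """
    sl = p.window_slice(window)
    w = p.mean_peth[sl]
    if w.size < smooth_bins:
        raise ValueError("window shorter than the smoothing kernel")
    half = smooth_bins // 2
    sm = np.array([w[max(0, i - half): i + half + 1].mean() for i in range(w.size)])
    return float(sm.max())


def smoothed_max(values: np.ndarray, smooth_bins: int = 3) -> np.ndarray:
    """Row-wise truncated moving-average maximum (vectorized batch form)."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    half = smooth_bins // 2
    n = v.shape[1]
    cols = []
    for i in range(n):
        cols.append(v[:, max(0, i - half): i + half + 1].mean(axis=1))
    return np.column_stack(cols).max(axis=1)


# ---------------------------------------------------------------------------
# I/O


def read_traces_h5(path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["neuron_ids"][...]]
        return TraceMatrix(
            session_id=str(f.attrs.get("session_id", "")),
            neuron_ids=ids,
            values=f["values"][...],
            sampling_rate=float(f["sampling_rate"][()]),
            zscored=bool(f.attrs.get("zscored", False)),
        )


def write_traces_h5(t: TraceMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=t.values)
        f.create_dataset("neuron_ids", data=np.array(t.neuron_ids, dtype="S"))
        f.create_dataset("sampling_rate", data=t.sampling_rate)
        f.attrs["session_id"] = t.session_id
        f.attrs["zscored"] = t.zscored


def read_traces_csv(path, session_id: str = "", sampling_rate: float = 10.0) -> TraceMatrix:
    """Wide delimited text: one column per neuron, one row per sample."""
    df = pd.read_csv(path, sep=None, engine="python")
    return TraceMatrix(session_id, [str(c) for c in df.columns],
                       df.to_numpy(float).T, sampling_rate)
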