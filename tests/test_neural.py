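"""Trace normalization, PETH construction, and modulation classification."""

import numpy as np
import pytest

from danseq.neural import (
    BASELINE_WINDOW,
    BIN_WIDTH,
    PETH_WINDOW,
    PethSet,
    TraceMatrix,
    build_peth,
    classify_modulation,
    classify_neuron,
    max_activity,
    modulation_mask,
    read_traces_csv,
    read_traces_h5,
    smoothed_max,
    write_traces_h5,
    zscore_traces,
)

N_BINS = int(round((PETH_WINDOW[1] - PETH_WINDOW[0]) / BIN_WIDTH))


def _peth(mean_values: np.ndarray, window=PETH_WINDOW) -> PethSet:
    edges = window[0] + BIN_WIDTH * np.arange(mean_values.size + 1)
    return PethSet("n0", "first_press", "contra", edges, mean_values[None, :])


def _flat_peth(bumps: dict[tuple[float, float], float]) -> PethSet:
    """Deterministic PETH: spread baseline bins, zero elsewhere, given bumps.

    The baseline spread fixes the 99th-percentile threshold just below 0.5,
    so bumps of |amplitude| > 1 are unambiguous and zeros never fire.
    """
    vals = np.zeros(N_BINS)
    p = _peth(vals)
    vals[p.window_slice(BASELINE_WINDOW)] = np.linspace(-0.5, 0.5, 50)
    for win, amp in bumps.items():
        sl = p.window_slice(win)
        vals[sl] += amp
    return p


# ---------------------------------------------------------------------------
# z-scoring


def test_zscore_example():
    t = TraceMatrix("s", ["a"], np.array([[0.0, 2.0]]))
    z = zscore_traces(t)
    assert np.allclose(z.values, [[-1.0, 1.0]])  # population sd convention
    assert z.zscored


def test_zscore_flat_row_and_reentry():
    t = TraceMatrix("s", ["a", "b"], np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
    z = zscore_traces(t)
    assert np.allclose(z.values[0], 0.0)
    assert z.values[1].mean() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        zscore_traces(z)


def test_tracematrix_validation():
    with pytest.raises(ValueError):
        TraceMatrix("s", ["a", "b"], np.zeros((1, 5)))
    with pytest.raises(ValueError):
        TraceMatrix("s", ["a"], np.array([[1.0, np.nan]]))


# ---------------------------------------------------------------------------
# PETH construction


def test_build_peth_bins_and_values():
    vals = np.arange(300.0)[None, :]  # 30 s at 10 Hz, ramp identifies samples
    t = TraceMatrix("s", ["a"], vals, sampling_rate=10.0, zscored=True)
    p = build_peth(t, [10.0], 0)
    assert p.trial_matrix.shape == (1, N_BINS)
    assert N_BINS == 140
    # one sample per 0.1-s bin: bin k holds sample (10 - 8) * 10 + k
    assert np.allclose(p.trial_matrix[0], np.arange(20, 160))
    assert p.bin_edges[0] == pytest.approx(-8.0)
    assert p.bin_edges[-1] == pytest.approx(6.0)


def test_build_peth_drops_out_of_bounds():
    t = TraceMatrix("s", ["a"], np.zeros((1, 300)), sampling_rate=10.0, zscored=True)
    p = build_peth(t, [1.0, 10.0, 29.0], 0)
    assert p.n_trials == 1
    assert p.n_dropped_trials == 2
    assert p.event_mask.tolist() == [False, True, False]


def test_build_peth_requires_zscored():
    t = TraceMatrix("s", ["a"], np.zeros((1, 300)), sampling_rate=10.0)
    with pytest.raises(ValueError):
        build_peth(t, [10.0], 0)


def test_window_slice_bounds():
    p = _peth(np.zeros(N_BINS))
    sl = p.window_slice((-2.0, 0.0))
    assert sl.stop - sl.start == 20
    with pytest.raises(ValueError):
        p.window_slice((-9.0, 0.0))


# ---------------------------------------------------------------------------
# modulation rule


def test_classify_modulation_consecutive_rule():
    two = _flat_peth({(-1.0, -0.8): 5.0})  # two consecutive elevated bins
    assert classify_modulation(two, (-2.0, 0.0))[0]
    assert classify_modulation(two, (-2.0, 0.0))[1] == "positive"
    one = _flat_peth({(-1.0, -0.9): 5.0})  # a single elevated bin
    assert not classify_modulation(one, (-2.0, 0.0))[0]
    neg = _flat_peth({(-1.0, -0.8): -5.0})
    assert classify_modulation(neg, (-2.0, 0.0))[1] == "negative"
    flat = _flat_peth({})
    assert not classify_modulation(flat, (-2.0, 0.0))[0]


def test_modulation_mask_agrees_with_single_rule():
    rng = np.random.default_rng(1)
    peths = rng.standard_normal((200, N_BINS))
    base = slice(0, 50)
    test = slice(60, 80)
    mask_pos = modulation_mask(peths, base, test, direction="positive")
    mask_neg = modulation_mask(peths, base, test, direction="negative")
    for i in range(200):
        is_mod, direction, _ = classify_modulation(_peth(peths[i]), (-2.0, 0.0))
        assert mask_pos[i] == (is_mod and direction == "positive")
        if not mask_pos[i]:
            assert mask_neg[i] == (is_mod and direction == "negative")


def test_classify_neuron_classes():
    movement = _flat_peth({(-1.5, -0.5): 5.0})
    execution = _flat_peth({(0.2, 0.8): 5.0})
    lick_reward = _flat_peth({(0.1, 0.7): 5.0})
    lick_magazine = _flat_peth({(-1.5, 0.7): 5.0})  # ramp through the lick
    flat = _flat_peth({})

    row = classify_neuron(movement, flat)
    assert row["movement"] and row["class"] == "movement_initiation"
    row = classify_neuron(execution, flat)
    assert row["execution"] and not row["movement"] and row["class"] == "execution"
    row = classify_neuron(flat, lick_reward)
    assert row["reward"] and not row["magazine_approach"] and row["class"] == "reward"
    row = classify_neuron(flat, lick_magazine)
    assert row["magazine_approach"] and not row["reward"]
    assert row["class"] == "magazine_approach"
    row = classify_neuron(None, flat)
    assert row["flagged_missing"]
    row = classify_neuron(movement, lick_reward)
    assert row["class"] == "movement_initiation"  # precedence


# ---------------------------------------------------------------------------
# peak activity


def test_max_activity_known_value():
    vals = np.array([0.0, 1.0, 2.0, 3.0, 0.0])
    edges = np.arange(6) * BIN_WIDTH
    p = PethSet("n", "first_press", "contra", edges, vals[None, :])
    # truncated centered 3-bin means: [.5, 1, 2, 5/3, 1.5] -> max 2.0
    assert max_activity(p, (0.0, 0.5)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        max_activity(p, (0.0, 0.2))  # window shorter than the kernel


def test_smoothed_max_matches_max_activity():
    rng = np.random.default_rng(3)
    vals = rng.standard_normal((10, 20))
    batch = smoothed_max(vals)
    for i in range(10):
        edges = np.arange(21) * BIN_WIDTH
        p = PethSet("n", "e", "c", edges, vals[i][None, :])
        assert batch[i] == pytest.approx(max_activity(p, (0.0, 2.0)))


# ---------------------------------------------------------------------------
# I/O


def test_h5_roundtrip(tmp_path):
    t = TraceMatrix("sess", ["a", "b"], np.random.default_rng(4).normal(size=(2, 50)),
                    sampling_rate=10.0, zscored=True)
    path = tmp_path / "traces.h5"
    write_traces_h5(t, path)
    back = read_traces_h5(path)
    assert back.session_id == "sess"
    assert back.neuron_ids == ["a", "b"]
    assert back.zscored
    assert np.allclose(back.values, t.values)


def test_read_traces_csv(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"n1": [0.0, 1.0], "n2": [2.0, 3.0]})
    path = tmp_path / "traces.csv"
    df.to_csv(path, index=False)
    t = read_traces_csv(path, "s", 10.0)
    assert t.values.shape == (2, 2)
    assert t.neuron_ids == ["n1", "n2"]
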