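"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the study design end to end: mice perform a fast
fixed-ratio lever-press task (4 presses in under 1 s earn a reward) in
bouts while their snout occupies a lever-side region of interest, once per
day with each forelimb, while one hemisphere's SNc dopamine neurons are
imaged at 10 Hz.  Planted neuron classes (movement-initiation, reward,
magazine-approach, execution; independent membership) produce
GCaMP6f-like double-exponential transients on a unit-variance noise
floor, with lateralized movement and magazine amplitudes, a
contralateral-only sequence-length amplitude gain, and a unilateral-lesion
epoch that shortens contralateral sequences only.

Default parameter values are the study's printed cohort-level values
(class fractions, per-side peak amplitudes, lesion cell means) or, where
no value is printed, literature-typical choices documented in the methods
note.  Movement amplitudes are specified on the trial-averaged PETH-peak
scale — the scale on which peak activity is measured — and converted to
per-event kernel amplitudes through the onset-jitter smearing factor.

Besides the full behavioral/trace simulation, fast cohort-level samplers
draw the quantities each population test consumes directly (per-neuron
peaks, per-bout activities, per-mouse lesion cell means, centroid sets,
stable PETH tuning) for calibration and power studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import EventLog, SequenceBout, assign_length_group, length_group_rank
from .neural import TraceMatrix
from .roi import RoiMap

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_paper_config",
    "simulate_behavior",
    "simulate_traces",
    "simulate_cohort",
    "simulate_lesion_cohort",
    "sample_amplitude_cohort",
    "sample_length_cohort",
    "sample_lesion_cells",
    "sample_matching_maps",
    "sample_stability_peths",
    "sample_null_peths",
    "kernel_smear_factor",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (times in s, activity in z)."""

    # cohort
    n_mice: int = 6
    n_neurons_total: int = 101
    sessions_per_condition: int = 1
    session_duration: float = 1800.0
    # behavior
    bout_rate_per_min: float = 3.0
    length_mean: float = 4.0
    length_support: tuple[int, int] = (1, 12)
    ipi_median: float = 0.30
    ipi_sigma: float = 0.30
    occupancy_pad: float = 0.3
    # reward -> approach -> first lick; long enough that press-related
    # transients stay out of the 2-s pre-lick classification window
    lick_latency: float = 2.5
    lick_latency_sigma: float = 0.6   # lognormal spread of the approach latency
    reward_n_presses: int = 4
    reward_window: float = 1.0
    # neurons
    sampling_rate: float = 10.0
    p_movement: float = 0.39
    p_reward: float = 0.37
    p_magazine: float = 0.15
    p_execution: float = 0.10
    independent_classes: bool = True
    rise_tau: float = 0.08
    decay_tau: float = 0.4
    amp_movement_contra: float = 0.646
    amp_movement_ipsi: float = 0.427
    amp_movement_cv: float = 0.55       # between-neuron lognormal CV (0.37/0.646)
    amp_reward: float = 1.0
    amp_reward_cv: float = 0.45
    amp_magazine_contra: float = 1.49
    amp_magazine_ipsi: float = 0.66
    amp_magazine_cv: float = 0.60
    trial_amp_sigma: float = 0.2        # lognormal per-event amplitude jitter
    length_gain: float = 0.31           # z per length-group step, coders only
    length_coder_frac: float = 0.27     # fraction of contra movement neurons
    length_ref_rank: int = 3            # gain anchored at group "4"
    movement_jitter: tuple[float, float] = (-1.5, -0.3)  # onset before first press
    noise_sd: float = 1.0
    # ROI geometry
    fov_px: float = 200.0
    min_spacing_px: float = 10.0
    centroid_jitter_px: float = 1.0
    detection_prob: float = 0.62        # per-session ROI recovery
    # lesion cohort
    n_lesion_mice: int = 8
    n_saline_mice: int = 6
    lesion_means: dict = field(
        default_factory=lambda: {
            ("before", "contra"): 4.12,
            ("after", "contra"): 2.17,
            ("before", "ipsi"): 4.13,
            ("after", "ipsi"): 3.52,
        }
    )
    saline_means: dict = field(
        default_factory=lambda: {
            ("before", "contra"): 3.40,
            ("after", "contra"): 2.73,
            ("before", "ipsi"): 3.06,
            ("after", "ipsi"): 2.46,
        }
    )
    lesion_sigma_mouse: float = 0.58    # between-mouse shift, shared by cells
    lesion_sigma_cell: float = 0.57     # per-cell departure (drives interaction power)

    def __post_init__(self) -> None:
        for p in (self.p_movement, self.p_reward, self.p_magazine, self.p_execution):
            if not (0.0 <= p <= 1.0):
                raise ValueError("class probabilities must lie in [0,1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("kernel taus must be positive")
        if self.bout_rate_per_min <= 0 or self.session_duration <= 0:
            raise ValueError("rates and durations must be positive")


def default_paper_config() -> SimulationConfig:
    """The default study conditions (all fields at their calibrated values)."""
    return SimulationConfig()


@dataclass
class GroundTruth:
    """Planted per-neuron identities; one row per neuron."""

    neurons: pd.DataFrame  # mouse_id, neuron_id, movement, reward, magazine, execution,
    #                        length_coder, amp factors

    def class_fraction(self, cls: str) -> float:
        return float(self.neurons[cls].mean())


# ---------------------------------------------------------------------------
# behavior


def _truncated_poisson(rng, mean: float, size: int, lo: int, hi: int) -> np.ndarray:
    """Shifted Poisson on [lo, hi]: lo + Poisson(mean - lo), resampling tails."""
    lam = max(mean - lo, 1e-9)
    out = lo + rng.poisson(lam, size=size)
    bad = out > hi
    while bad.any():
        out[bad] = lo + rng.poisson(lam, size=int(bad.sum()))
        bad = out > hi
    return out


def _bout_lengths(rng, cfg: SimulationConfig, n: int, mean: float | None = None) -> np.ndarray:
    lo, hi = cfg.length_support
    return _truncated_poisson(rng, cfg.length_mean if mean is None else mean, n, lo, hi)


def _one_session(
    rng,
    cfg: SimulationConfig,
    session_id: str,
    mouse_id: str,
    day: int,
    lever_side: str,
    hemisphere: str,
    length_mean: float | None = None,
    epoch: str = "none",
    treatment: str = "none",
) -> EventLog:
    dur = cfg.session_duration
    n_bouts = int(dur / 60.0 * cfg.bout_rate_per_min)
    spacing = dur / n_bouts
    if spacing < 12.0:
        raise ValueError("bout rate too high for the peri-event windows")
    onsets = spacing * np.arange(n_bouts) + rng.uniform(0.45 * spacing, 0.7 * spacing, n_bouts)
    lengths = _bout_lengths(rng, cfg, n_bouts, length_mean)

    press, occ, rewards, licks = [], [], [], []
    for t0, k in zip(onsets, lengths):
        ipis = rng.lognormal(math.log(cfg.ipi_median), cfg.ipi_sigma, size=max(k - 1, 0))
        times = t0 + np.concatenate([[0.0], np.cumsum(ipis)])
        if times[-1] + 6.0 > dur:  # keep full post-event windows inside the session
            continue
        press.append(times)
        occ.append((times[0] - cfg.occupancy_pad, times[-1] + cfg.occupancy_pad))
        # FR4/1-s rule: reward at the press completing the first qualifying run
        n_req, win = cfg.reward_n_presses, cfg.reward_window
        if times.size >= n_req:
            spans = times[n_req - 1:] - times[: times.size - n_req + 1]
            hit = np.flatnonzero(spans < win)
            if hit.size:
                r = float(times[hit[0] + n_req - 1])
                lk = r + rng.lognormal(math.log(cfg.lick_latency), cfg.lick_latency_sigma)
                if lk + 6.0 <= dur:  # keep the full post-lick window inside the session
                    rewards.append(r)
                    licks.append(lk)
    return EventLog(
        session_id=session_id,
        mouse_id=mouse_id,
        day_index=day,
        lever_side=lever_side,
        hemisphere=hemisphere,
        epoch=epoch,
        treatment=treatment,
        press_times=np.concatenate(press) if press else np.empty(0),
        lick_times=np.asarray(licks),
        reward_times=np.asarray(rewards),
        occupancy_intervals=np.asarray(occ).reshape(-1, 2),
        session_duration=dur,
    )


def simulate_behavior(cfg: SimulationConfig, seed: int) -> list[EventLog]:
    """Imaging-cohort behavior: each mouse, each day, one session per forelimb."""
    rng = np.random.default_rng(seed)
    logs = []
    for m in range(cfg.n_mice):
        mouse = f"m{m:02d}"
        hemi = "left" if m % 2 == 0 else "right"
        for day in range(cfg.sessions_per_condition):
            for lever in ("left", "right"):
                sid = f"{mouse}_d{day}_{lever}"
                logs.append(
                    _one_session(rng, cfg, sid, mouse, day, lever, hemi)
                )
    return logs


# ---------------------------------------------------------------------------
# neurons and traces


def _kernel(cfg: SimulationConfig) -> np.ndarray:
    fs = cfg.sampling_rate
    t = np.arange(0.0, 6.0 * cfg.decay_tau, 1.0 / fs)
    k = (1.0 - np.exp(-t / cfg.rise_tau)) * np.exp(-t / cfg.decay_tau)
    return k / k.max()


def kernel_smear_factor(cfg: SimulationConfig) -> float:
    """Peak of the trial-averaged kernel under uniform onset jitter.

    Movement transients start uniformly inside ``movement_jitter`` relative
    to the first press, so the mean PETH is the kernel averaged over those
    offsets; a planted PETH-peak amplitude ``a`` needs per-event amplitude
    ``a / smear``.
    """
    fs = cfg.sampling_rate
    k = _kernel(cfg)
    lo, hi = cfg.movement_jitter
    offsets = np.arange(int(round(lo * fs)), int(round(hi * fs)) + 1)
    span = offsets.max() - offsets.min() + k.size
    acc = np.zeros(span)
    for o in offsets - offsets.min():
        acc[o: o + k.size] += k
    return float(acc.max() / offsets.size)


def _plant_classes(cfg: SimulationConfig, rng) -> GroundTruth:
    per_mouse = np.full(cfg.n_mice, cfg.n_neurons_total // cfg.n_mice)
    per_mouse[: cfg.n_neurons_total % cfg.n_mice] += 1
    rows = []
    for m in range(cfg.n_mice):
        mouse = f"m{m:02d}"
        for j in range(per_mouse[m]):
            mov = rng.random() < cfg.p_movement
            # reward and magazine-approach are alternative shapes of the same
            # lick-aligned response (peak-only vs pre-lick ramp), so one
            # categorical draw covers both; movement membership stays
            # independent, which is what the overlap-vs-chance test assumes.
            p_rew = cfg.p_reward
            if not cfg.independent_classes:
                # dependence knob: movement neurons twice as likely to carry a
                # reward response, marginal reward fraction preserved
                boost = min(2.0 * cfg.p_reward, 1.0)
                p_rew = boost if mov else max(
                    (cfg.p_reward - cfg.p_movement * boost) / (1.0 - cfg.p_movement), 0.0
                )
            u = rng.random()
            rew = u < p_rew
            mag = (not rew) and u < p_rew + cfg.p_magazine
            exe = rng.random() < cfg.p_execution
            rows.append(
                {
                    "mouse_id": mouse,
                    "neuron_id": f"{mouse}_n{j:02d}",
                    "movement": mov,
                    "reward": rew,
                    "magazine": mag,
                    "execution": exe,
                    "length_coder": bool(mov and rng.random() < cfg.length_coder_frac),
                    # shared neuron-level amplitude factors (lognormal, mean 1)
                    "f_movement": _lognorm_factor(rng, cfg.amp_movement_cv),
                    "f_reward": _lognorm_factor(rng, cfg.amp_reward_cv),
                    "f_magazine": _lognorm_factor(rng, cfg.amp_magazine_cv),
                }
            )
    return GroundTruth(pd.DataFrame(rows))


def _lognorm_factor(rng, cv: float) -> float:
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))


def _trial_amp(rng, cfg: SimulationConfig, size: int) -> np.ndarray:
    s = cfg.trial_amp_sigma
    return rng.lognormal(-s * s / 2.0, s, size=size)


def simulate_traces(
    cfg: SimulationConfig, logs: list[EventLog], truth: GroundTruth, seed: int
) -> tuple[dict[str, TraceMatrix], dict[str, RoiMap]]:
    """Event-driven traces and per-session ROI maps for an imaging cohort."""
    rng = np.random.default_rng(seed)
    kern = _kernel(cfg)
    smear = kernel_smear_factor(cfg)
    fs = cfg.sampling_rate
    traces: dict[str, TraceMatrix] = {}
    rois: dict[str, RoiMap] = {}
    base_centroids = {}
    for mouse, sub in truth.neurons.groupby("mouse_id"):
        base_centroids[mouse] = _spaced_centroids(rng, len(sub), cfg)

    for log in logs:
        sub = truth.neurons[truth.neurons.mouse_id == log.mouse_id].reset_index(drop=True)
        n = len(sub)
        n_samp = int(round(cfg.session_duration * fs))
        v = rng.normal(0.0, cfg.noise_sd, size=(n, n_samp))
        limb = log.limb
        amp_mov = cfg.amp_movement_contra if limb == "contra" else cfg.amp_movement_ipsi
        amp_mag = cfg.amp_magazine_contra if limb == "contra" else cfg.amp_magazine_ipsi

        from .behavior import segment_sequences

        bouts = segment_sequences(log)
        first = np.array([b.start for b in bouts])
        ranks = np.array([length_group_rank(b.length_group) for b in bouts])
        last = np.array([b.end for b in bouts])
        licks = log.lick_times

        for i in range(n):
            row = sub.iloc[i]
            if row.movement and first.size:
                jit = rng.uniform(*cfg.movement_jitter, size=first.size)
                amps = amp_mov * row.f_movement / smear * _trial_amp(rng, cfg, first.size)
                if row.length_coder and limb == "contra":
                    amps = amps + cfg.length_gain / smear * (ranks - cfg.length_ref_rank)
                    amps = np.maximum(amps, 0.0)
                _add_transients(v[i], first + jit, amps, kern, fs)
            if row.execution and first.size:
                t_exec = rng.uniform(first, np.maximum(last, first + 0.1))
                amps = 0.8 * _trial_amp(rng, cfg, first.size)
                _add_transients(v[i], t_exec, amps, kern, fs)
            if row.reward and licks.size:
                amps = cfg.amp_reward * row.f_reward * _trial_amp(rng, cfg, licks.size)
                _add_transients(v[i], licks, amps, kern, fs)
            if row.magazine and licks.size:
                amps = amp_mag * row.f_magazine * _trial_amp(rng, cfg, licks.size)
                _add_ramps(v[i], licks, amps, cfg, fs)

        traces[log.session_id] = TraceMatrix(
            log.session_id, list(sub.neuron_id), v, fs, zscored=False
        )
        jitter = rng.normal(0.0, cfg.centroid_jitter_px, size=(n, 2))
        rois[log.session_id] = RoiMap(
            log.session_id, list(sub.neuron_id), base_centroids[log.mouse_id] + jitter
        )
    return traces, rois


def _add_transients(row: np.ndarray, times, amps, kern: np.ndarray, fs: float) -> None:
    starts = np.round(np.asarray(times) * fs).astype(int)
    for s, a in zip(starts, np.broadcast_to(amps, starts.shape)):
        if s < 0 or s >= row.size:
            continue
        end = min(s + kern.size, row.size)
        row[s:end] += a * kern[: end - s]


def _add_ramps(row: np.ndarray, lick_times, amps, cfg: SimulationConfig, fs: float) -> None:
    ramp_len = int(round(2.0 * fs))
    ramp = np.linspace(0.0, 1.0, ramp_len, endpoint=True)
    decay = np.exp(-np.arange(int(round(2.0 * fs))) / (cfg.decay_tau * fs))
    shape = np.concatenate([ramp, decay[1:]])
    starts = np.round((np.asarray(lick_times) - 2.0) * fs).astype(int)
    for s, a in zip(starts, np.broadcast_to(amps, starts.shape)):
        if s < 0:
            continue
        end = min(s + shape.size, row.size)
        row[s:end] += a * shape[: end - s]


def _spaced_centroids(rng, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Rejection-sample centroids at least ``min_spacing_px`` apart."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(0.0, cfg.fov_px, size=2)
        if all(np.linalg.norm(cand - p) >= cfg.min_spacing_px for p in pts):
            pts.append(cand)
        tries += 1
        if tries > 100_000:
            raise RuntimeError("cannot place centroids at requested spacing")
    return np.asarray(pts)


def simulate_cohort(cfg: SimulationConfig, seed: int):
    """Behavior + planted neurons + traces + ROI maps in one call."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_cls, s_tr = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    logs = simulate_behavior(cfg, s_beh)
    truth = _plant_classes(cfg, np.random.default_rng(s_cls))
    traces, rois = simulate_traces(cfg, logs, truth, s_tr)
    return logs, truth, traces, rois


# ---------------------------------------------------------------------------
# lesion cohort


def simulate_lesion_cohort(cfg: SimulationConfig, seed: int, group: str = "6OHDA") -> list[EventLog]:
    """Before/after x limb behavior for a treatment group.

    Per-mouse cell mean lengths are the planted cell means plus a shared
    mouse shift (sigma_mouse) plus an independent per-cell departure
    (sigma_cell); bout lengths are then drawn around each cell mean.
    """
    rng = np.random.default_rng(seed)
    means = cfg.lesion_means if group == "6OHDA" else cfg.saline_means
    n_mice = cfg.n_lesion_mice if group == "6OHDA" else cfg.n_saline_mice
    logs = []
    for m in range(n_mice):
        mouse = f"{group}_m{m:02d}"
        hemi = "left" if m % 2 == 0 else "right"
        shift = rng.normal(0.0, cfg.lesion_sigma_mouse)
        for epoch in ("before", "after"):
            for lever in ("left", "right"):
                limb = "contra" if lever != hemi else "ipsi"
                mu = means[(epoch, limb)] + shift + rng.normal(0.0, cfg.lesion_sigma_cell)
                mu = max(mu, 1.05)
                sid = f"{mouse}_{epoch}_{lever}"
                logs.append(
                    _one_session(
                        rng, cfg, sid, mouse, 0, lever, hemi,
                        length_mean=mu, epoch=epoch, treatment=group,
                    )
                )
    return logs


# ---------------------------------------------------------------------------
# fast cohort-level samplers (calibration and power studies)


def sample_amplitude_cohort(
    rng,
    n_contra: int = 37,
    n_ipsi: int = 33,
    mean_contra: float = 0.646,
    mean_ipsi: float = 0.427,
    sem_contra: float = 0.061,
    sem_ipsi: float = 0.059,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron peak pre-press activities at the printed means and SEMs."""
    sd_c = sem_contra * math.sqrt(n_contra)
    sd_i = sem_ipsi * math.sqrt(n_ipsi)
    return (
        rng.normal(mean_contra, sd_c, size=n_contra),
        rng.normal(mean_ipsi, sd_i, size=n_ipsi),
    )


def sample_length_cohort(
    rng,
    cfg: SimulationConfig | None = None,
    n_neurons: int = 37,
    n_bouts: int = 90,
    planted_gain: float | None = None,
    coder_frac: float | None = None,
    trial_sd: float = 1.0,
):
    """Per-bout peak activities for a movement-neuron cohort.

    Returns (per-neuron list of (activities, lengths), group-mean matrix).
    ``planted_gain`` of 0 gives the null (ipsi-like) generator.
    """
    cfg = cfg or default_paper_config()
    gain = cfg.length_gain if planted_gain is None else planted_gain
    frac = cfg.length_coder_frac if coder_frac is None else coder_frac
    per_neuron = []
    n_groups = 6
    gm = np.full((n_neurons, n_groups), np.nan)
    for i in range(n_neurons):
        base = rng.normal(cfg.amp_movement_contra, cfg.amp_movement_contra * cfg.amp_movement_cv)
        coder = rng.random() < frac
        lengths = _bout_lengths(rng, cfg, n_bouts)
        ranks = np.array([length_group_rank(assign_length_group(n)) for n in lengths])
        act = base + (gain * (ranks - cfg.length_ref_rank) if coder else 0.0)
        act = act + rng.normal(0.0, trial_sd, size=n_bouts)
        per_neuron.append((act, lengths))
        for g in range(n_groups):
            sel = ranks == g + 1
            if sel.any():
                gm[i, g] = act[sel].mean()
    return per_neuron, gm


def sample_lesion_cells(
    rng, cfg: SimulationConfig | None = None, group: str = "6OHDA"
) -> np.ndarray:
    """(n_mice, time, limb) per-mouse mean presses/sequence, SEM-calibrated."""
    cfg = cfg or default_paper_config()
    means = cfg.lesion_means if group == "6OHDA" else cfg.saline_means
    n = cfg.n_lesion_mice if group == "6OHDA" else cfg.n_saline_mice
    mu = np.array(
        [[means[(e, l)] for l in ("contra", "ipsi")] for e in ("before", "after")]
    )
    shift = rng.normal(0.0, cfg.lesion_sigma_mouse, size=(n, 1, 1))
    noise = rng.normal(0.0, cfg.lesion_sigma_cell, size=(n, 2, 2))
    return np.maximum(mu[None] + shift + noise, 1.0)


def sample_matching_maps(
    rng,
    cfg: SimulationConfig | None = None,
    n_rois: int = 100,
    n_sessions: int = 2,
    detection_prob: float = 1.0,
) -> tuple[list[RoiMap], np.ndarray]:
    """Jittered per-session centroid maps of one field of view.

    Returns the maps plus the (n_rois, n_sessions) detection mask; ROI ids
    encode true identity so recovery can be scored.
    """
    cfg = cfg or default_paper_config()
    base = _spaced_centroids(rng, n_rois, cfg)
    present = rng.random((n_rois, n_sessions)) < detection_prob
    maps = []
    for s in range(n_sessions):
        sel = np.flatnonzero(present[:, s])
        jit = rng.normal(0.0, cfg.centroid_jitter_px, size=(sel.size, 2))
        maps.append(
            RoiMap(f"day{s}", [f"roi{i:03d}" for i in sel], base[sel] + jit)
        )
    return maps, present


def sample_stability_peths(
    rng,
    n_rois: int = 30,
    n_sessions: int = 3,
    n_bins: int = 160,
    tuning_sd: float = 1.0,
    session_noise_sd: float = 0.69,
    smooth_bins: int = 4,
    events: tuple[str, ...] = ("press_contra", "press_ipsi", "lick_contra", "lick_ipsi"),
) -> list[list[dict]]:
    """Stable-tuning PETH cohort: shared smooth tuning + per-session noise.

    Returns ``peths[roi][session] -> {event: vector}``.  The noise level
    defaults to a matched-pair Spearman correlation near the observed 0.68.
    """

    def smooth(x):
        k = np.ones(smooth_bins) / smooth_bins
        return np.convolve(x, k, mode="same")

    out = []
    for _ in range(n_rois):
        tunings = {ev: tuning_sd * smooth(rng.normal(size=n_bins)) / (1 / math.sqrt(smooth_bins))
                   for ev in events}
        sessions = []
        for _s in range(n_sessions):
            sessions.append(
                {
                    ev: t + session_noise_sd * smooth(rng.normal(size=n_bins)) * math.sqrt(smooth_bins)
                    for ev, t in tunings.items()
                }
            )
        out.append(sessions)
    return out


def sample_null_peths(rng, n: int, n_bins: int = 140) -> np.ndarray:
    """Exchangeable null mean PETHs: iid standard-normal bins."""
    return rng.normal(size=(n, n_bins))


def null_config(cfg: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of the config with all planted effects removed."""
    cfg = cfg or default_paper_config()
    return replace(
        cfg,
        p_movement=0.0, p_reward=0.0, p_magazine=0.0, p_execution=0.0,
        length_gain=0.0, length_coder_frac=0.0,
    )
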