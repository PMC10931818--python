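"""End-to-end orchestration: simulate -> segment -> classify -> analyze.

`run_pipeline` executes the stages on a synthetic cohort from a single
config and seed, and returns a nested report plus a flat one-row-per-
statistic table.  Each stage is also callable on its own with real data
frames (event logs, traces, ROI maps) read from disk.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import behavior as beh
from . import neural, population, roi
from .lesion import LesionDataset, lesion_stats
from .simulate import (
    SimulationConfig,
    default_paper_config,
    sample_matching_maps,
    sample_stability_peths,
    simulate_cohort,
    simulate_lesion_cohort,
)
from .stats import TestResult

logger = logging.getLogger("danseq")

__all__ = ["classify_session", "classify_cohort", "run_pipeline", "report_frame"]


def classify_session(
    log: beh.EventLog,
    traces: neural.TraceMatrix,
    pre_window: tuple[float, float] = neural.PRE_PRESS_WINDOW,
    peak_window: tuple[float, float] = (-2.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every neuron of one session.

    Returns (modtable rows, per-bout peak table).  The per-bout table holds
    each neuron's smoothed peak pre-press activity for every bout, with the
    bout length — the input to the sequence-length analyses.
    """
    z = neural.zscore_traces(traces) if not traces.zscored else traces
    bouts = beh.segment_sequences(log)
    first = np.array([b.start for b in bouts])
    lengths = np.array([b.n_presses for b in bouts])
    licks = log.lick_times
    cond = log.limb

    mod_rows, bout_rows = [], []
    for i, nid in enumerate(z.neuron_ids):
        p_press = neural.build_peth(z, first, i, "first_press", cond) if first.size else None
        p_lick = neural.build_peth(z, licks, i, "rewarded_lick", cond) if licks.size else None
        row = neural.classify_neuron(p_press, p_lick, pre_window=pre_window)
        row["neuron_id"] = nid
        row["condition"] = cond
        row["mouse_id"] = log.mouse_id
        row["session_id"] = log.session_id
        if p_press is not None and p_press.n_trials:
            sl = p_press.window_slice(peak_window)
            peaks = neural.smoothed_max(p_press.trial_matrix[:, sl])
            row["max_pre_press"] = neural.max_activity(p_press, peak_window)
            kept = lengths[p_press.event_mask]
            for pk, ln in zip(peaks, kept):
                bout_rows.append(
                    {"neuron_id": nid, "mouse_id": log.mouse_id, "condition": cond,
                     "n_presses": int(ln), "peak": float(pk)}
                )
        mod_rows.append(row)
    return pd.DataFrame(mod_rows), pd.DataFrame(bout_rows)


def classify_cohort(
    logs: list[beh.EventLog],
    traces: dict[str, neural.TraceMatrix],
    pre_window=neural.PRE_PRESS_WINDOW,
    peak_window=(-2.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    mods, peaks = [], []
    for log in logs:
        m, p = classify_session(log, traces[log.session_id], pre_window, peak_window)
        mods.append(m)
        peaks.append(p)
    return pd.concat(mods, ignore_index=True), pd.concat(peaks, ignore_index=True)


def _population_stage(modtable: pd.DataFrame, bout_peaks: pd.DataFrame) -> dict:
    out: dict = {}
    summary = population.population_summary(modtable)
    out["summary"] = summary
    out["class_fractions"] = {
        cls: float(modtable[col].mean())
        for cls, col in (("movement", "movement"), ("reward", "reward"),
                         ("magazine_approach", "magazine_approach"))
    }
    try:
        out["proportion_contrast"] = population.proportion_contrast(summary, "movement")
    except ValueError as e:
        logger.warning("proportion contrast skipped: %s", e)
    mov = modtable[modtable.movement]
    contra = mov.loc[mov.condition == "contra", "max_pre_press"].dropna().to_numpy()
    ipsi = mov.loc[mov.condition == "ipsi", "max_pre_press"].dropna().to_numpy()
    if contra.size >= 2 and ipsi.size >= 2:
        out["amplitude_contrast"] = population.amplitude_contrast(contra, ipsi)
        out["mean_peak"] = {"contra": float(contra.mean()), "ipsi": float(ipsi.mean())}

    # sequence-length coding among movement neurons
    length_results, counts = [], {"contra": [0, 0], "ipsi": [0, 0]}
    mov_ids = set(zip(mov.neuron_id, mov.condition))
    for (nid, cond), grp in bout_peaks.groupby(["neuron_id", "condition"]):
        if (nid, cond) not in mov_ids:
            continue
        try:
            r = population.length_modulation(nid, cond, grp["peak"], grp["n_presses"])
        except ValueError:
            continue
        length_results.append(r)
        counts[cond][1] += 1
        counts[cond][0] += int(r.positively_modulated)
    out["length_results"] = length_results
    out["length_counts"] = counts
    for cond in ("contra", "ipsi"):
        gm = np.array([r.group_means for r in length_results if r.condition == cond])
        if gm.shape[0] >= 3:
            out[f"length_trend_{cond}"] = population.length_trend(gm)
    if min(counts["contra"][1], counts["ipsi"][1]) > 0:
        out["length_proportion"] = population.length_proportion_contrast(
            counts["contra"][0], counts["contra"][1],
            counts["ipsi"][0], counts["ipsi"][1],
        )
    out["overlap"] = population.overlap_analysis(modtable, "contra")
    out["reward_laterality"] = population.reward_laterality(modtable)
    return out


def _matching_stage(cfg: SimulationConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    maps3, present = sample_matching_maps(
        rng, cfg, n_rois=120, n_sessions=3, detection_prob=cfg.detection_prob
    )
    pair_sessions = [(0, 1), (0, 2), (1, 2)]
    matched_in = {}
    for a_i, b_i in pair_sessions:
        mt = roi.match_sessions(maps3[a_i], maps3[b_i], max_dist=5.0)
        for ra, rb, _ in mt.pairs:
            if ra == rb:  # true identity encoded in the id
                matched_in.setdefault(ra, set()).update({a_i, b_i})
    n_any2 = sum(1 for s in matched_in.values() if len(s) >= 2)
    n_all3 = sum(1 for s in matched_in.values() if len(s) == 3)
    summary = roi.match_summary(n_all3, n_any2)

    peths = sample_stability_peths(rng, n_rois=40)
    records = []
    for k, sessions in enumerate(peths):
        others = [p for j, p in enumerate(peths) if j != k]
        records.append({"roi": f"r{k}", "group": "matched",
                        "value": roi.crossday_peth_correlation(sessions)})
        records.append({"roi": f"r{k}", "group": "shuffled",
                        "value": roi.control_correlations(
                            sessions, mode="shuffled",
                            seed=int(rng.integers(2**31)))})
        records.append({"roi": f"r{k}", "group": "different",
                        "value": roi.control_correlations(
                            sessions, others, mode="different")})
    stability = roi.stability_summary(pd.DataFrame(records))
    return {"match_summary": summary, "stability": stability}


def _lesion_stage(cfg: SimulationConfig, seed: int) -> dict:
    out = {}
    for i, group in enumerate(("6OHDA", "saline")):
        logs = simulate_lesion_cohort(cfg, seed + i, group)
        frames = [beh.bouts_to_frame(beh.segment_sequences(lg)) for lg in logs]
        bouts = pd.concat(frames, ignore_index=True)
        manifest = pd.DataFrame(
            {
                "session_id": [lg.session_id for lg in logs],
                "mouse_id": [lg.mouse_id for lg in logs],
                "epoch": [lg.epoch for lg in logs],
                "treatment": [lg.treatment for lg in logs],
                "limb": [lg.limb for lg in logs],
            }
        )
        ds = LesionDataset.from_frame(bouts, manifest)
        out[group] = lesion_stats(ds, group)
    return out


def run_pipeline(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    stages: tuple[str, ...] = ("behavior", "classify", "population", "matching", "lesion"),
) -> dict:
    """Run the toggled stages on a synthetic cohort; returns the report."""
    cfg = cfg or default_paper_config()
    logger.info("run_pipeline seed=%d config=%s", seed, dataclasses.asdict(cfg))
    report: dict = {"seed": seed, "config": dataclasses.asdict(cfg)}
    logs = truth = traces = None
    if {"behavior", "classify", "population"} & set(stages):
        logs, truth, traces, _rois = simulate_cohort(cfg, seed)
        report["ground_truth_fractions"] = {
            cls: truth.class_fraction(cls)
            for cls in ("movement", "reward", "magazine", "execution")
        }
    if "behavior" in stages:
        rows = []
        for log in logs:
            bouts = beh.segment_sequences(log)
            m = beh.behavior_metrics(log, bouts)
            rows.append({"session_id": log.session_id, **dataclasses.asdict(m)})
        report["behavior"] = pd.DataFrame(rows)
    if "classify" in stages:
        modtable, bout_peaks = classify_cohort(logs, traces)
        report["modtable"] = modtable
        report["bout_peaks"] = bout_peaks
    if "population" in stages:
        report["population"] = _population_stage(report["modtable"], report["bout_peaks"])
    if "matching" in stages:
        report["matching"] = _matching_stage(cfg, seed + 101)
    if "lesion" in stages:
        report["lesion"] = _lesion_stage(cfg, seed + 202)
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a pipeline report into one row per headline statistic."""
    rows: list[dict] = []

    def add(stage, name, value, **kw):
        rows.append({"stage": stage, "statistic": name, "value": value, **kw})

    def add_test(stage, name, t: TestResult):
        add(stage, f"{name}_statistic", t.statistic, p=t.p_value)

    if "behavior" in report:
        b = report["behavior"]
        add("behavior", "mean_presses_per_sequence", b["mean_presses_per_sequence"].mean())
        add("behavior", "mean_ipi", b["ipi_mean"].mean())
        add("behavior", "mean_ipi_fano", b["ipi_fano"].mean())
    pop = report.get("population", {})
    for cls, frac in pop.get("class_fractions", {}).items():
        add("population", f"fraction_{cls}", frac)
    for key in ("proportion_contrast", "amplitude_contrast", "overlap",
                "length_proportion", "length_trend_contra", "length_trend_ipsi"):
        if key in pop:
            add_test("population", key, pop[key])
    if "matching" in report:
        ms = report["matching"]["match_summary"]
        add("matching", "pct_matched_all_sessions", ms["pct_matched_all_sessions"])
        for g, v in report["matching"]["stability"]["group_means"].items():
            add("matching", f"stability_{g}_mean", v)
    for group, res in report.get("lesion", {}).items():
        for measure in ("mean_presses", "pct_long"):
            an = res[measure]["anova"]
            for factor, d in an.factors.items():
                add("lesion", f"{group}_{measure}_{factor}_F", d["F"], p=d["p"])
    return pd.DataFrame(rows)
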