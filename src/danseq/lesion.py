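"""Unilateral dopamine-depletion behavioral contrast (before/after x limb).

Each mouse is measured in four cells — before/after treatment crossed with
contralateral/ipsilateral forelimb (relative to the lesioned hemisphere).
Per cell the analysis computes the mean presses/sequence and the percentage
of long sequences, where "long" means strictly more presses than that
mouse's own baseline (pre-treatment) mean for the same forelimb.  Per
treatment group the summaries enter a two-way repeated-measures ANOVA with
Sidak-adjusted before/after post hocs per limb; after/before ratios of the
per-mouse means are compared between limbs with a paired t and against the
no-change value 1 with one-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import SequenceBout
from .stats import AnovaTable, TestResult, rm_anova_2x2, t_tests

__all__ = ["LesionDataset", "long_sequence_threshold", "lesion_stats"]

EPOCHS = ("before", "after")
LIMBS = ("contra", "ipsi")


@dataclass
class LesionDataset:
    """bouts[mouse_id][(epoch, limb)] -> list of SequenceBout; group per mouse."""

    group: dict[str, str]  # mouse_id -> {"6OHDA", "saline"}
    bouts: dict[str, dict[tuple[str, str], list[SequenceBout]]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, manifest: pd.DataFrame) -> "LesionDataset":
        """Build from a tidy bouts table joined with a sessions manifest.

        ``df`` needs columns session_id, n_presses (press_times optional);
        ``manifest`` needs session_id, mouse_id, epoch, treatment and the
        limb of each session (column 'limb' or lever_side+hemisphere).
        """
        man = manifest.copy()
        if "limb" not in man.columns:
            man["limb"] = np.where(
                man["lever_side"] != man["hemisphere"], "contra", "ipsi"
            )
        joined = df.merge(man[["session_id", "mouse_id", "epoch", "treatment", "limb"]],
                          on="session_id", how="left", suffixes=("", "_m"))
        if joined["mouse_id"].isna().any():
            raise ValueError("bouts reference sessions missing from manifest")
        group = dict(man.groupby("mouse_id")["treatment"].first())
        bouts: dict[str, dict[tuple[str, str], list[SequenceBout]]] = {}
        for (mouse, epoch, limb), sub in joined.groupby(["mouse_id", "epoch", "limb"]):
            cell = bouts.setdefault(mouse, {})
            cell[(epoch, limb)] = [
                SequenceBout(np.arange(n, dtype=float), limb=limb, session_id=str(s))
                for n, s in zip(sub["n_presses"], sub["session_id"])
            ]
        return cls(group, bouts)


def long_sequence_threshold(baseline_bouts: list[SequenceBout]) -> float:
    """Per-mouse, per-forelimb threshold: mean baseline presses/sequence.

    A post-treatment sequence is "long" when its length is strictly greater
    than this threshold.
    """
    if not baseline_bouts:
        raise ValueError("empty baseline")
    return float(np.mean([b.n_presses for b in baseline_bouts]))


def _cell_means(ds: LesionDataset, mouse: str):
    lengths = {}
    for epoch in EPOCHS:
        for limb in LIMBS:
            cell = ds.bouts.get(mouse, {}).get((epoch, limb), [])
            if not cell:
                return None
            lengths[(epoch, limb)] = np.array([b.n_presses for b in cell], float)
    return lengths


def lesion_stats(ds: LesionDataset, group: str = "6OHDA") -> dict:
    """Full before/after x limb analysis for one treatment group.

    Returns per-mouse summaries plus, for both mean presses/sequence and
    percent long sequences: the 2x2 repeated-measures ANOVA (with Sidak
    post hocs), the paired contra-vs-ipsi test on after/before ratios, and
    one-sample t tests of each limb's ratio against 1.
    """
    mice = sorted(m for m, g in ds.group.items() if g == group)
    rows = []
    excluded = []
    for mouse in mice:
        lengths = _cell_means(ds, mouse)
        if lengths is None:
            excluded.append(mouse)
            continue
        rec = {"mouse_id": mouse}
        for limb in LIMBS:
            thr = float(np.mean(lengths[("before", limb)]))
            for epoch in EPOCHS:
                x = lengths[(epoch, limb)]
                rec[f"mean_{epoch}_{limb}"] = float(x.mean())
                rec[f"pctlong_{epoch}_{limb}"] = 100.0 * float(np.mean(x > thr))
            rec[f"ratio_mean_{limb}"] = rec[f"mean_after_{limb}"] / rec[f"mean_before_{limb}"]
            base_long = rec[f"pctlong_before_{limb}"]
            rec[f"ratio_pctlong_{limb}"] = (
                rec[f"pctlong_after_{limb}"] / base_long if base_long > 0 else np.nan
            )
        rows.append(rec)
    if len(rows) < 2:
        raise ValueError("need >= 2 complete mice per group")
    summary = pd.DataFrame(rows)

    out = {"summary": summary, "excluded_mice": excluded, "group": group}
    for measure, prefix in (("mean_presses", "mean"), ("pct_long", "pctlong")):
        cube = np.stack(
            [
                np.array(
                    [
                        [summary[f"{prefix}_{e}_{l}"].iloc[i] for l in LIMBS]
                        for e in EPOCHS
                    ]
                )
                for i in range(len(summary))
            ]
        )  # (mice, time, limb)
        anova: AnovaTable = rm_anova_2x2(cube, factor_names=("time", "forelimb"))
        tests: dict[str, TestResult] = {}
        rc = summary[f"ratio_{prefix}_contra"].to_numpy(float)
        ri = summary[f"ratio_{prefix}_ipsi"].to_numpy(float)
        ok = np.isfinite(rc) & np.isfinite(ri)
        if ok.sum() >= 2:
            tests["ratio_paired_contra_vs_ipsi"] = t_tests(rc[ok], ri[ok], mode="paired")
            tests["ratio_contra_vs_1"] = t_tests(rc[ok], mode="one_sample_vs_mu", mu=1.0)
            tests["ratio_ipsi_vs_1"] = t_tests(ri[ok], mode="one_sample_vs_mu", mu=1.0)
        out[measure] = {"anova": anova, "tests": tests}
    return out
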