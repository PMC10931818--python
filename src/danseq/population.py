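"""Population statistics: modulated-neuron proportions, laterality, length coding.

Per-mouse class percentages are compared between contralateral and
ipsilateral performance with paired t tests; neuron-level peak activities
are pooled across mice and compared with pooled-variance unpaired t tests
(mouse identity is retained in the tidy outputs for sensitivity checks).
Sequence-length coding uses the grouped lengths (<=2, 3, 4, 5, 6, 7+)
mapped to ordinal ranks: per neuron a Spearman correlation between per-bout
peak pre-press activity and length rank (positively length-modulated means
rho > 0 at p < 0.05), and at the population level a post-ANOVA linear-trend
contrast on the neuron x length-group mean-activity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LENGTH_GROUPS, length_group_rank
from .stats import (
    TestResult,
    fisher_exact_2x2,
    linear_trend_contrast,
    overlap_chance_test,
    spearman,
    t_tests,
)

__all__ = [
    "LengthModulationResult",
    "proportion_contrast",
    "amplitude_contrast",
    "length_modulation",
    "length_trend",
    "length_proportion_contrast",
    "reward_laterality",
    "overlap_analysis",
    "population_summary",
]


@dataclass
class LengthModulationResult:
    neuron_id: str
    condition: str
    rho: float
    p: float
    positively_modulated: bool
    group_means: np.ndarray  # mean peak activity per length group (NaN when absent)

    def __post_init__(self) -> None:
        if self.positively_modulated and not (self.rho > 0 and self.p < 0.05):
            raise ValueError("positively_modulated requires rho > 0 and p < 0.05")


# ---------------------------------------------------------------------------
# class proportions and amplitudes


def population_summary(modtable: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse, per-condition class percentages from a ModulationTable.

    Expects columns: mouse_id, condition, movement, reward,
    magazine_approach (booleans, one row per neuron x condition).
    """
    def pct(g):
        return pd.Series(
            {
                "n_neurons": len(g),
                "pct_movement": 100.0 * g["movement"].mean(),
                "pct_reward": 100.0 * g["reward"].mean(),
                "pct_magazine_approach": 100.0 * g["magazine_approach"].mean(),
            }
        )

    return (
        modtable.groupby(["mouse_id", "condition"])[
            ["movement", "reward", "magazine_approach"]
        ]
        .apply(pct)
        .reset_index()
    )


def proportion_contrast(summary: pd.DataFrame, cls: str = "movement") -> TestResult:
    """Paired t test on per-mouse class percentages, contra vs ipsi."""
    col = f"pct_{cls}"
    wide = summary.pivot(index="mouse_id", columns="condition", values=col).dropna()
    if wide.shape[0] < 2:
        raise ValueError("need >= 2 mice with both conditions")
    return t_tests(wide["contra"].to_numpy(), wide["ipsi"].to_numpy(), mode="paired")


def amplitude_contrast(max_acts_contra, max_acts_ipsi) -> TestResult:
    """Unpaired t on neuron-level peak pre-event activity, contra vs ipsi."""
    a = np.asarray(max_acts_contra, dtype=float)
    b = np.asarray(max_acts_ipsi, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 neurons per side")
    return t_tests(a, b, mode="unpaired")


# ---------------------------------------------------------------------------
# sequence-length coding


def length_modulation(
    neuron_id: str,
    condition: str,
    bout_max_activity,
    bout_lengths,
    exact_threshold: int = 8,
) -> LengthModulationResult:
    """Per-neuron Spearman between per-bout peak activity and length rank."""
    act = np.asarray(bout_max_activity, dtype=float)
    lengths = np.asarray(bout_lengths, dtype=int)
    if act.shape != lengths.shape:
        raise ValueError("activity/length mismatch")
    from .behavior import assign_length_group

    groups = np.array([assign_length_group(n) for n in lengths])
    ranks = np.array([length_group_rank(g) for g in groups], dtype=float)
    if np.unique(ranks).size < 3:
        raise ValueError("fewer than 3 length groups represented: unclassifiable")
    res = spearman(ranks, act, exact_threshold=exact_threshold)
    gm = np.full(len(LENGTH_GROUPS), np.nan)
    for i, g in enumerate(LENGTH_GROUPS):
        sel = groups == g
        if sel.any():
            gm[i] = act[sel].mean()
    return LengthModulationResult(
        neuron_id=neuron_id,
        condition=condition,
        rho=res.statistic,
        p=res.p_value,
        positively_modulated=bool(res.statistic > 0 and res.p_value < 0.05),
        group_means=gm,
    )


def length_trend(group_means_matrix) -> TestResult:
    """Linear-trend contrast on a neurons x length-group mean matrix."""
    return linear_trend_contrast(group_means_matrix)


def length_proportion_contrast(
    n_mod_contra: int, n_contra: int, n_mod_ipsi: int, n_ipsi: int
) -> TestResult:
    """Fisher exact on length-modulated proportions, contra vs ipsi."""
    if n_mod_contra > n_contra or n_mod_ipsi > n_ipsi:
        raise ValueError("modulated counts exceed totals")
    return fisher_exact_2x2(
        [[n_mod_contra, n_contra - n_mod_contra], [n_mod_ipsi, n_ipsi - n_mod_ipsi]]
    )


# ---------------------------------------------------------------------------
# reward / magazine-approach laterality and population overlap


def reward_laterality(modtable: pd.DataFrame) -> dict[str, TestResult]:
    """Laterality tests for the reward and magazine-approach classes.

    For each class: a paired t on per-mouse percentages (contra vs ipsi)
    and a pooled unpaired t on neuron-level peaks (post-reward peak for the
    reward class, pre-lick peak for magazine approach).  Empty classes are
    skipped with a notice entry.
    """
    out: dict[str, TestResult] = {}
    summary = population_summary(modtable)
    for cls, peak_col in (("reward", "max_post_lick"), ("magazine_approach", "max_pre_lick")):
        sub = modtable[modtable[cls]]
        if sub.empty or sub["condition"].nunique() < 2:
            out[f"{cls}_skipped"] = TestResult(f"{cls}_skipped", 0.0, 1.0,
                                               extra={"notice": "class empty"})
            continue
        contra = sub.loc[sub.condition == "contra", peak_col].to_numpy(float)
        ipsi = sub.loc[sub.condition == "ipsi", peak_col].to_numpy(float)
        try:
            out[f"{cls}_proportion"] = proportion_contrast(summary, cls)
            out[f"{cls}_amplitude"] = amplitude_contrast(contra, ipsi)
        except ValueError as e:  # too few mice or neurons on one side
            out[f"{cls}_skipped"] = TestResult(f"{cls}_skipped", 0.0, 1.0,
                                               extra={"notice": str(e)})
    return out


def overlap_analysis(modtable: pd.DataFrame, condition: str = "contra") -> TestResult:
    """Movement/reward population overlap vs independent-membership chance."""
    sub = modtable[modtable.condition == condition]
    n_total = len(sub)
    n_mov = int(sub["movement"].sum())
    n_rew = int(sub["reward"].sum())
    n_both = int((sub["movement"] & sub["reward"]).sum())
    return overlap_chance_test(n_mov, n_rew, n_both, n_total)
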