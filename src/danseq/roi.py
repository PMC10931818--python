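"""Cross-session ROI matching and functional-stability controls.

Single-photon miniscope fields of view drift little day to day, so the same
cell can be re-identified across sessions from its ROI centroid.  Matching
is a mutual-nearest-neighbor rule with a distance gate (an automated
surrogate for shape inspection), resolved greedily by ascending distance so
it is one-to-one.  Functional stability is the maximum Spearman correlation
between a matched pair's event-aligned PETHs over up to four events (first
press and rewarded lick, contralateral and ipsilateral), averaged across
session pairs on the Fisher-Z scale, against two controls: the matched
PETH shuffled in time (random circular rotation), and the best-correlated
non-matched ROI of the same animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist
from statsmodels.stats.anova import AnovaRM

from .stats import TestResult, fisher_z_mean

__all__ = [
    "RoiMap",
    "MatchTable",
    "match_sessions",
    "crossday_peth_correlation",
    "control_correlations",
    "stability_summary",
    "match_summary",
]

CORRELATION_WINDOW = (-10.0, 6.0)  # PETH span used for stability correlations


@dataclass
class RoiMap:
    session_id: str
    roi_ids: list[str]
    centroids: np.ndarray  # (n, 2) pixels

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if len(self.roi_ids) != len(set(self.roi_ids)):
            raise ValueError("duplicate roi_ids in one session")
        if self.centroids.shape[0] != len(self.roi_ids):
            raise ValueError("centroid/id length mismatch")
        if not np.isfinite(self.centroids).all():
            raise ValueError("non-finite centroid")


@dataclass
class MatchTable:
    session_a: str
    session_b: str
    pairs: list[tuple[str, str, float]] = field(default_factory=list)  # (roi_a, roi_b, dist)
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["roi_a", "roi_b", "distance"])


def match_sessions(
    a: RoiMap, b: RoiMap, max_dist: float = 5.0, k_candidates: int = 3
) -> MatchTable:
    """Pair ROIs of two sessions by centroid proximity.

    A pair is accepted when the two ROIs are mutual nearest neighbors and
    closer than ``max_dist`` pixels; conflicts are resolved greedily by
    ascending distance.  ``k_candidates`` nearest candidates per reference
    ROI are retained in the distance computation (diagnostic parity with a
    manual shape check of the closest few candidates).
    """
    if not a.roi_ids or not b.roi_ids:
        raise ValueError("empty RoiMap")
    d = cdist(a.centroids, b.centroids)
    nn_a = d.argmin(axis=1)
    nn_b = d.argmin(axis=0)
    candidates = [
        (d[i, j], i, j)
        for i, j in enumerate(nn_a)
        if nn_b[j] == i and d[i, j] <= max_dist
    ]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, i, j in sorted(candidates):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a.roi_ids[i], b.roi_ids[j], float(dist)))
    return MatchTable(
        a.session_id,
        b.session_id,
        pairs,
        [r for i, r in enumerate(a.roi_ids) if i not in used_a],
        [r for j, r in enumerate(b.roi_ids) if j not in used_b],
    )


def match_summary(n_matched_all: int, n_matched_any: int) -> dict:
    """Cohort summary: fraction of plotted ROIs recovered in every session."""
    if not (0 <= n_matched_all <= n_matched_any):
        raise ValueError("inconsistent match counts")
    pct = 100.0 * n_matched_all / n_matched_any if n_matched_any else float("nan")
    return {"n_matched_all": n_matched_all, "n_matched_any": n_matched_any,
            "pct_matched_all_sessions": pct}


# ---------------------------------------------------------------------------
# PETH correlations


def _max_event_spearman(peths_a: dict, peths_b: dict) -> float:
    """Max over shared events of the Spearman correlation of mean PETHs."""
    shared = sorted(set(peths_a) & set(peths_b))
    if not shared:
        raise ValueError("no shared event PETHs")
    best = -1.0
    for ev in shared:
        x = np.asarray(peths_a[ev], dtype=float)
        y = np.asarray(peths_b[ev], dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"PETH binning differs for event {ev!r}")
        rho = sps.spearmanr(x, y).statistic
        if np.isnan(rho):
            rho = 0.0
        best = max(best, float(rho))
    return best


def crossday_peth_correlation(peths_by_session: list[dict]) -> float:
    """Stability of one ROI matched across 2+ sessions.

    ``peths_by_session[s]`` maps event labels (up to 4: press/lick x
    contra/ipsi) to that session's mean PETH vector.  Each session pair
    contributes the maximum Spearman correlation over shared events; pairs
    are combined with a Fisher-Z average.
    """
    if len(peths_by_session) < 2:
        raise ValueError("need PETHs from at least two sessions")
    vals = [
        _max_event_spearman(peths_by_session[i], peths_by_session[j])
        for i in range(len(peths_by_session))
        for j in range(i + 1, len(peths_by_session))
    ]
    return fisher_z_mean(vals)


def control_correlations(
    ref_peths: list[dict],
    all_rois_peths: list[list[dict]] | None = None,
    mode: str = "shuffled",
    seed: int | None = None,
    min_shift_bins: int = 10,
) -> float:
    """Control value for one reference ROI.

    mode='shuffled': each non-reference session's PETHs are circularly
    rotated by a random offset of at least ``min_shift_bins`` bins (>= 1 s
    at 0.1-s bins) before the pairwise max-correlations are averaged.
    mode='different': for each session pair, the best cross-day correlation
    achievable with any *other* ROI of the same animal, averaged.
    """
    rng = np.random.default_rng(seed)
    n_s = len(ref_peths)
    if n_s < 2:
        raise ValueError("need at least two sessions")
    if mode == "shuffled":
        vals = []
        for i in range(n_s):
            for j in range(i + 1, n_s):
                rolled = {}
                for ev, p in ref_peths[j].items():
                    p = np.asarray(p, dtype=float)
                    if p.size <= min_shift_bins:
                        raise ValueError("PETH too short for the minimum shift")
                    k = int(rng.integers(min_shift_bins, p.size))
                    rolled[ev] = np.roll(p, k)
                vals.append(_max_event_spearman(ref_peths[i], rolled))
        return fisher_z_mean(vals)
    if mode == "different":
        if not all_rois_peths or len(all_rois_peths) < 1:
            raise ValueError("different-mode needs other ROIs of the same animal")
        vals = []
        for i in range(n_s):
            for j in range(i + 1, n_s):
                best = max(
                    _max_event_spearman(ref_peths[i], other[j])
                    for other in all_rois_peths
                )
                vals.append(best)
        return fisher_z_mean(vals)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# stability summary


def stability_summary(records: pd.DataFrame, strong_threshold: float = 0.5) -> dict:
    """Group Fisher-Z means, RM one-way ANOVA on Z values, Tukey post hoc.

    ``records`` is tidy with columns (roi, group, value), group in
    {matched, shuffled, different}; ROIs missing any group are dropped and
    counted.  The ANOVA is computed on the Fisher-Z transformed
    correlations with ROI as the repeated-measures unit; Tukey comparisons
    use the studentized range on the within-ROI error term.
    """
    required = {"matched", "shuffled", "different"}
    wide = records.pivot_table(index="roi", columns="group", values="value")
    n_before = wide.shape[0]
    wide = wide.dropna(subset=sorted(required & set(wide.columns)))
    missing_groups = required - set(wide.columns)
    if missing_groups:
        raise ValueError(f"missing groups: {sorted(missing_groups)}")
    n_dropped = n_before - wide.shape[0]
    if wide.shape[0] < 2:
        raise ValueError("stability ANOVA needs >= 2 complete ROIs")

    z = np.arctanh(np.clip(wide[["matched", "shuffled", "different"]].to_numpy(), -1 + 1e-6, 1 - 1e-6))
    n, k = z.shape
    long = pd.DataFrame(
        {
            "roi": np.repeat(wide.index.to_numpy(), k),
            "group": np.tile(["matched", "shuffled", "different"], n),
            "z": z.ravel(),
        }
    )
    aov = AnovaRM(long, depvar="z", subject="roi", within=["group"]).fit().anova_table
    f = float(aov.loc["group", "F Value"])
    p = float(aov.loc["group", "Pr > F"])
    df1, df2 = float(aov.loc["group", "Num DF"]), float(aov.loc["group", "Den DF"])

    # Tukey HSD on the repeated-measures error term
    grand = z.mean()
    subj = z.mean(axis=1, keepdims=True)
    grp = z.mean(axis=0, keepdims=True)
    resid = z - subj - grp + grand
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid ** 2).sum() / df_err)
    se = np.sqrt(ms_err / n)
    names = ["matched", "shuffled", "different"]
    tukey = []
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            q = abs(grp[0, a_i] - grp[0, b_i]) / se
            p_t = float(sps.studentized_range.sf(q, k, df_err))
            tukey.append(
                TestResult("tukey_rm", float(q), min(p_t, 1.0),
                           df=(float(k), float(df_err)),
                           extra={"contrast": f"{names[a_i]} vs {names[b_i]}"})
            )

    group_means = {g: fisher_z_mean(wide[g].to_numpy()) for g in names}
    frac_strong = float((wide["matched"] > strong_threshold).mean())
    return {
        "group_means": group_means,
        "anova": {"F": f, "df": (df1, df2), "p": p},
        "tukey": tukey,
        "fraction_matched_above_threshold": frac_strong,
        "n_rois": n,
        "n_dropped_incomplete": n_dropped,
    }
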