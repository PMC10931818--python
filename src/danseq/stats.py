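"""Statistical primitives shared by every analysis stage.

Small, self-contained wrappers and hand-rolled tests chosen to match the
conventions of classical behavioral-neuroscience statistics: pooled-variance
t tests, exact permutation Spearman p at small n, two-sided Fisher exact,
within-subject 2x2 repeated-measures ANOVA with Sidak-adjusted paired
post hocs, a post-ANOVA linear-trend contrast for ordered groups, Fisher-Z
averaging of correlations, and a hypergeometric population-overlap test.

Every p-value is two-sided unless a contrast is explicitly directional.
Sample (n-1) variance is used throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AnovaTable",
    "spearman",
    "fisher_exact_2x2",
    "t_tests",
    "rm_anova_2x2",
    "linear_trend_contrast",
    "fisher_z_mean",
    "overlap_chance_test",
    "sidak_adjust",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    __test__ = False  # not a test-collection target

    test: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect_direction: str = "none"  # {"positive", "negative", "none"}
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"non-finite statistic in {self.test}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1] in {self.test}")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class AnovaTable:
    """Per-factor F tests (factor -> dict with F, df_num, df_den, p)."""

    factors: dict[str, dict[str, float]]
    posthoc: list[TestResult] = field(default_factory=list)

    def __getitem__(self, factor: str) -> dict[str, float]:
        return self.factors[factor]


# ---------------------------------------------------------------------------
# rank correlation


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        return 0.0
    return float(rx @ ry) / denom


def spearman(x, y, exact_threshold: int = 8) -> TestResult:
    """Spearman rank correlation with exact permutation p at small n.

    Ties are mid-ranked.  For n <= ``exact_threshold`` the two-sided p-value
    is the fraction of the n! permutations of ``y`` whose |rho| is at least
    the observed |rho|; above the threshold the large-sample t approximation
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n <= exact_threshold:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        if denom == 0.0:
            p = 1.0
        else:
            rhos = (ry_c[perms] @ rx_c) / denom
            p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    direction = "positive" if rho > 0 else ("negative" if rho < 0 else "none")
    return TestResult("spearman", rho, min(p, 1.0), df=n - 2, effect_direction=direction)


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if t.sum() == 0:
        raise ValueError("empty table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    if not np.isfinite(odds):
        odds = float(t.sum())  # degenerate odds ratio; statistic kept finite
    direction = "positive" if odds > 1 else ("negative" if odds < 1 else "none")
    return TestResult("fisher_exact", float(odds), float(p), effect_direction=direction)


def overlap_chance_test(
    n_a: int, n_b: int, n_both: int, n_total: int, n_perm: int = 0, seed: int | None = None
) -> TestResult:
    """Is the overlap between two cell populations different from chance?

    Under independent membership the overlap of a size-``n_a`` and a size-
    ``n_b`` subset of ``n_total`` cells is hypergeometric; the two-sided p
    sums the probabilities of all overlaps at most as likely as the observed
    one.  ``n_perm > 0`` replaces the exact distribution with a Monte-Carlo
    permutation of the label assignment (mainly a cross-check).
    """
    if not (0 <= n_both <= min(n_a, n_b) <= n_total) or max(n_a, n_b) > n_total:
        raise ValueError("inconsistent overlap counts")
    expected = n_a * n_b / n_total if n_total > 0 else 0.0
    if n_a == 0 or n_b == 0:
        return TestResult("overlap_chance", 0.0, 1.0, extra={"expected": expected})
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(n_a, n_total - n_a, n_b, size=n_perm)
        pmf_obs = sps.hypergeom.pmf(n_both, n_total, n_a, n_b)
        pmf_draws = sps.hypergeom.pmf(draws, n_total, n_a, n_b)
        p = float(np.mean(pmf_draws <= pmf_obs * (1 + 1e-9)))
    else:
        k = np.arange(max(0, n_a + n_b - n_total), min(n_a, n_b) + 1)
        pmf = sps.hypergeom.pmf(k, n_total, n_a, n_b)
        pmf_obs = sps.hypergeom.pmf(n_both, n_total, n_a, n_b)
        p = float(pmf[pmf <= pmf_obs * (1 + 1e-9)].sum())
    direction = (
        "positive" if n_both > expected else ("negative" if n_both < expected else "none")
    )
    return TestResult(
        "overlap_chance",
        float(n_both),
        min(p, 1.0),
        effect_direction=direction,
        extra={"expected": expected},
    )


# ---------------------------------------------------------------------------
# t tests


def t_tests(a, b=None, mode: str = "unpaired", mu: float = 0.0) -> TestResult:
    """Classical t tests: pooled-variance unpaired, paired, or one-sample.

    Zero-variance inputs with identical means return statistic 0, p = 1 and
    are flagged in ``extra['degenerate']``.
    """
    a = np.asarray(a, dtype=float)
    degenerate = False
    if mode == "one_sample_vs_mu":
        if a.size < 2:
            raise ValueError("one-sample t requires n >= 2")
        if np.std(a, ddof=1) == 0.0:
            if a[0] == mu:
                return TestResult("t_one_sample", 0.0, 1.0, df=a.size - 1,
                                  extra={"degenerate": True})
            raise ValueError("zero variance with mean != mu: t undefined")
        t, p = sps.ttest_1samp(a, mu)
        df = a.size - 1
    else:
        b = np.asarray(b, dtype=float)
        if mode == "paired":
            if a.shape != b.shape:
                raise ValueError("paired t requires equal lengths")
            d = a - b
            if np.std(d, ddof=1) == 0.0:
                if d[0] == 0.0:
                    return TestResult("t_paired", 0.0, 1.0, df=a.size - 1,
                                      extra={"degenerate": True})
                raise ValueError("constant nonzero paired difference: t undefined")
            t, p = sps.ttest_rel(a, b)
            df = a.size - 1
        elif mode == "unpaired":
            if a.size < 2 or b.size < 2:
                raise ValueError("unpaired t requires n >= 2 per group")
            if np.std(a, ddof=1) == 0.0 and np.std(b, ddof=1) == 0.0:
                if a.mean() == b.mean():
                    return TestResult("t_unpaired", 0.0, 1.0, df=a.size + b.size - 2,
                                      extra={"degenerate": True})
                raise ValueError("zero variance with different means: t undefined")
            # pooled variance, no Welch correction
            t, p = sps.ttest_ind(a, b, equal_var=True)
            df = a.size + b.size - 2
        else:
            raise ValueError(f"unknown mode {mode!r}")
    direction = "positive" if t > 0 else ("negative" if t < 0 else "none")
    return TestResult(f"t_{mode}", float(t), float(p), df=float(df),
                      effect_direction=direction, extra={"degenerate": degenerate})


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment for one of ``m`` comparisons."""
    return float(1.0 - (1.0 - min(p, 1.0)) ** m)


# ---------------------------------------------------------------------------
# repeated-measures 2x2 ANOVA

def rm_anova_2x2(values, factor_names: tuple[str, str] = ("time", "forelimb")) -> AnovaTable:
    """Two-way fully within-subject ANOVA on an (n_subjects, 2, 2) array.

    ``values[s, i, j]`` is subject ``s`` at level ``i`` of the first factor
    and level ``j`` of the second.  Each effect is tested against its own
    subject-by-factor interaction error term (the standard univariate
    within-subject decomposition; with two levels per factor, sphericity is
    not an issue).  Companion Sidak-adjusted paired contrasts of the first
    factor within each level of the second are attached as ``posthoc``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape[1:] != (2, 2):
        raise ValueError("values must have shape (n_subjects, 2, 2)")
    if np.isnan(v).any():
        raise ValueError("missing cell in repeated-measures design")
    n = v.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")

    grand = v.mean()
    subj = v.mean(axis=(1, 2))        # (n,)
    a_m = v.mean(axis=(0, 2))         # (2,) first-factor marginal means
    b_m = v.mean(axis=(0, 1))         # (2,)
    ab_m = v.mean(axis=0)             # (2, 2)
    sa = v.mean(axis=2)               # (n, 2) subject x A
    sb = v.mean(axis=1)               # (n, 2) subject x B

    ss_a = 2 * n * ((a_m - grand) ** 2).sum()
    ss_b = 2 * n * ((b_m - grand) ** 2).sum()
    ss_ab = n * ((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    ss_sa = 2 * ((sa - subj[:, None] - a_m[None, :] + grand) ** 2).sum()
    ss_sb = 2 * ((sb - subj[:, None] - b_m[None, :] + grand) ** 2).sum()
    ss_tot = ((v - grand) ** 2).sum()
    ss_subj = 4 * ((subj - grand) ** 2).sum()
    ss_sab = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    df_e = n - 1
    factors = {}
    for name, ss_eff, ss_err in (
        (factor_names[0], ss_a, ss_sa),
        (factor_names[1], ss_b, ss_sb),
        (f"{factor_names[0]}x{factor_names[1]}", ss_ab, ss_sab),
    ):
        ms_err = ss_err / df_e
        f = ss_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, 1, df_e)) if ms_err > 0 else 1.0
        factors[name] = {"F": max(f, 0.0), "df_num": 1, "df_den": df_e, "p": p}

    posthoc = []
    for j in range(2):
        res = t_tests(v[:, 0, j], v[:, 1, j], mode="paired")
        res.extra["p_adjusted"] = sidak_adjust(res.p_value, 2)
        res.extra["contrast"] = f"{factor_names[0]} within {factor_names[1]}={j}"
        posthoc.append(res)
    return AnovaTable(factors, posthoc)


# ---------------------------------------------------------------------------
# linear-trend contrast across ordered groups


def linear_trend_contrast(group_means) -> TestResult:
    """Post-hoc test for linear trend across ordered groups.

    ``group_means`` is (units x groups); each cell enters a one-way ANOVA
    with equally spaced contrast coefficients across the ordered groups,
    F = SS_contrast / MSE on (1, N - k) degrees of freedom.  NaN cells
    (unit missing a group) are dropped, mirroring unbalanced designs.
    """
    m = np.asarray(group_means, dtype=float)
    if m.ndim == 1:
        m = m[None, :]
    k = m.shape[1]
    if k < 3:
        raise ValueError("linear trend requires >= 3 ordered groups")
    coef = np.arange(k, dtype=float) - (k - 1) / 2.0
    n_j = (~np.isnan(m)).sum(axis=0)
    if (n_j == 0).any():
        raise ValueError("a group has no observations")
    ybar_j = np.nanmean(m, axis=0)
    n_obs = int(n_j.sum())
    df_err = n_obs - k
    if df_err <= 0:
        raise ValueError("not enough observations for error term")
    ss_err = np.nansum((m - ybar_j[None, :]) ** 2)
    mse = ss_err / df_err
    est = float(coef @ ybar_j)
    ss_contrast = est ** 2 / float((coef ** 2 / n_j).sum())
    f = ss_contrast / mse if mse > 0 else 0.0
    p = float(sps.f.sf(f, 1, df_err)) if mse > 0 else (1.0 if est == 0 else 0.0)
    direction = "positive" if est > 0 else ("negative" if est < 0 else "none")
    return TestResult("linear_trend", float(f), p, df=(1.0, float(df_err)),
                      effect_direction=direction, extra={"slope_estimate": est})


# ---------------------------------------------------------------------------
# correlation averaging


def fisher_z_mean(r) -> float:
    """Average correlations on the Fisher-Z scale: tanh(mean(atanh(r))).

    Inputs at exactly +/-1 are clipped to +/-(1 - 1e-6).
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty correlation vector")
    if (np.abs(r) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -1 + 1e-6, 1 - 1e-6)
    return float(np.tanh(np.mean(np.arctanh(r))))
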