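"""Statistical primitives: worked examples plus independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from danseq.stats import (
    TestResult,
    fisher_exact_2x2,
    fisher_z_mean,
    linear_trend_contrast,
    overlap_chance_test,
    rm_anova_2x2,
    sidak_adjust,
    spearman,
    t_tests,
)


# ---------------------------------------------------------------------------
# TestResult invariants


def test_testresult_rejects_bad_values():
    with pytest.raises(ValueError):
        TestResult("t", float("nan"), 0.5)
    with pytest.raises(ValueError):
        TestResult("t", 1.0, 1.5)
    assert TestResult("t", 1.0, 0.01).significant
    assert not TestResult("t", 1.0, 0.2).significant


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_monotone_exact_p():
    res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert res.statistic == pytest.approx(1.0)
    # only the identity and the full reversal reach |rho| = 1
    assert res.p_value == pytest.approx(2 / 120)
    assert res.effect_direction == "positive"


def test_spearman_matches_scipy_rho():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


def test_spearman_exact_p_vs_enumeration_oracle():
    rng = np.random.default_rng(1)
    for _ in range(5):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= abs(obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert res.p_value == pytest.approx(count / math.factorial(6), abs=1e-12)


def test_spearman_ties_midranked():
    res = spearman([1, 1, 2, 3], [1, 2, 3, 4])
    rx = np.array([1.5, 1.5, 3, 4])
    ry = np.array([1.0, 2, 3, 4])
    expected = np.corrcoef(rx, ry)[0, 1]
    assert res.statistic == pytest.approx(expected)


def test_spearman_input_validation():
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# Fisher exact and overlap


def test_fisher_exact_known_value():
    res = fisher_exact_2x2([[3, 1], [1, 3]])
    assert res.p_value == pytest.approx(0.485714285714, abs=1e-9)
    assert res.effect_direction == "positive"


def test_fisher_exact_validation():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [0, 0]])


def test_overlap_expected_and_edges():
    res = overlap_chance_test(5, 4, 2, 10)
    assert res.extra["expected"] == pytest.approx(2.0)
    assert res.statistic == 2.0
    # empty population on one side is trivially chance-consistent
    assert overlap_chance_test(0, 4, 0, 10).p_value == 1.0
    with pytest.raises(ValueError):
        overlap_chance_test(5, 4, 5, 10)  # overlap exceeds the smaller set


def test_overlap_exact_vs_enumeration_oracle():
    # two-sided exact p: sum of hypergeometric pmf over outcomes at most
    # as likely as the observed overlap, enumerated directly here
    for n_total, n_a, n_b, n_both in [(20, 8, 6, 1), (30, 10, 15, 8), (12, 5, 5, 4)]:
        res = overlap_chance_test(n_a, n_b, n_both, n_total)
        pmf = {
            k: math.comb(n_a, k) * math.comb(n_total - n_a, n_b - k) / math.comb(n_total, n_b)
            for k in range(max(0, n_a + n_b - n_total), min(n_a, n_b) + 1)
        }
        p_ref = sum(v for v in pmf.values() if v <= pmf[n_both] * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_overlap_monte_carlo_agrees_with_exact():
    exact = overlap_chance_test(10, 12, 2, 40)
    mc = overlap_chance_test(10, 12, 2, 40, n_perm=40_000, seed=0)
    assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)


# ---------------------------------------------------------------------------
# t tests


def test_unpaired_t_known_value():
    res = t_tests([1, 2, 3], [4, 5, 6], mode="unpaired")
    assert res.statistic == pytest.approx(-3.674234614, abs=1e-8)
    assert res.p_value == pytest.approx(0.021311641, abs=1e-8)
    assert res.df == 4.0


def test_paired_t_known_value():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([1.5, 2.5, 2.5, 4.5])
    res = t_tests(a, b, mode="paired")
    assert res.statistic == pytest.approx(-1.0)
    assert res.p_value == pytest.approx(2 * sps.t.sf(1.0, 3), abs=1e-12)


def test_one_sample_t():
    res = t_tests([1.0, 2.0, 3.0], mode="one_sample_vs_mu", mu=0.0)
    assert res.statistic == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-9)
    assert t_tests([1.0, 2.0, 3.0], mode="one_sample_vs_mu", mu=2.0).statistic == 0.0


def test_t_degenerate_cases():
    res = t_tests([2.0, 2.0], [2.0, 2.0], mode="unpaired")
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.extra["degenerate"]
    with pytest.raises(ValueError):
        t_tests([2.0, 2.0], [3.0, 3.0], mode="unpaired")
    with pytest.raises(ValueError):
        t_tests([1.0, 2.0], mode="bogus")


def test_sidak():
    assert sidak_adjust(0.05, 2) == pytest.approx(0.0975)
    assert sidak_adjust(1.0, 3) == 1.0


# ---------------------------------------------------------------------------
# repeated-measures 2x2 ANOVA


def _anova_rm_oracle(v: np.ndarray) -> dict:
    n = v.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 4),
            "A": np.tile([0, 0, 1, 1], n),
            "B": np.tile([0, 1, 0, 1], n),
            "y": v.reshape(-1),
        }
    )
    tab = AnovaRM(long, depvar="y", subject="subject", within=["A", "B"]).fit().anova_table
    return {
        "A": (tab.loc["A", "F Value"], tab.loc["A", "Pr > F"]),
        "B": (tab.loc["B", "F Value"], tab.loc["B", "Pr > F"]),
        "AB": (tab.loc["A:B", "F Value"], tab.loc["A:B", "Pr > F"]),
    }


def test_rm_anova_matches_statsmodels():
    rng = np.random.default_rng(2)
    for _ in range(5):
        v = rng.normal(size=(8, 2, 2)) + rng.normal(size=(8, 1, 1))
        table = rm_anova_2x2(v, factor_names=("A", "B"))
        ref = _anova_rm_oracle(v)
        for mine, theirs in (("A", "A"), ("B", "B"), ("AxB", "AB")):
            assert table[mine]["F"] == pytest.approx(ref[theirs][0], abs=1e-8)
            assert table[mine]["p"] == pytest.approx(ref[theirs][1], abs=1e-8)
            assert table[mine]["df_den"] == 7


def test_rm_anova_posthoc_adjusted():
    rng = np.random.default_rng(3)
    table = rm_anova_2x2(rng.normal(size=(6, 2, 2)))
    assert len(table.posthoc) == 2
    for res in table.posthoc:
        assert res.extra["p_adjusted"] >= res.p_value - 1e-12


def test_rm_anova_validation():
    with pytest.raises(ValueError):
        rm_anova_2x2(np.zeros((4, 2, 3)))
    bad = np.zeros((4, 2, 2))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        rm_anova_2x2(bad)


# ---------------------------------------------------------------------------
# linear-trend contrast


def test_linear_trend_vs_ols_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    for _ in range(5):
        m = rng.normal(size=(12, 4)) + 0.3 * np.arange(4)
        m[rng.random(m.shape) < 0.15] = np.nan  # unbalanced cells
        if (np.sum(~np.isnan(m), axis=0) == 0).any():
            continue
        res = linear_trend_contrast(m)
        rows = [(val, g) for row in m for g, val in enumerate(row) if not np.isnan(val)]
        y = np.array([r[0] for r in rows])
        g = np.array([r[1] for r in rows])
        x = np.zeros((y.size, 4))
        x[np.arange(y.size), g] = 1.0
        fit = sm.OLS(y, x).fit()
        coef = np.arange(4) - 1.5
        ftest = fit.f_test(coef)
        assert res.statistic == pytest.approx(float(ftest.fvalue), abs=1e-8)
        assert res.p_value == pytest.approx(float(ftest.pvalue), abs=1e-8)


def test_linear_trend_direction_and_validation():
    up = linear_trend_contrast(np.tile(np.arange(4.0), (5, 1)) + np.random.default_rng(5).normal(0, 0.1, (5, 4)))
    assert up.effect_direction == "positive" and up.significant
    with pytest.raises(ValueError):
        linear_trend_contrast(np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# Fisher-Z averaging


def test_fisher_z_mean_values():
    expected = math.tanh((math.atanh(0.3) + math.atanh(0.7)) / 2)
    assert fisher_z_mean([0.3, 0.7]) == pytest.approx(expected)
    assert fisher_z_mean([0.3, 0.7]) == pytest.approx(0.528751, abs=1e-5)
    assert fisher_z_mean([0.5, -0.5]) == pytest.approx(0.0, abs=1e-12)
    assert fisher_z_mean([1.0]) == pytest.approx(1.0, abs=1e-5)  # clipped, not inf


def test_fisher_z_mean_validation():
    with pytest.raises(ValueError):
        fisher_z_mean([])
    with pytest.raises(ValueError):
        fisher_z_mean([1.2])
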