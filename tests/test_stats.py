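"""Rank tests, logistic regression, 2x2 odds ratios and their cross-checks."""

import numpy as np
import pytest
from scipy import stats as sps

from pcosmet.stats import (
    SeparationError,
    TwoByTwo,
    friedman,
    group_comparison,
    logistic_fit,
    mann_whitney,
    pearson_r,
    two_by_two_or,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mw_exact_small_sample():
    res = mann_whitney([1, 2], [3, 4])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3, abs=1e-4)
    assert "exact" in res.method


def test_mw_identical_multisets_u_is_half():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    res = mann_whitney(x, x)
    assert res.statistic == len(x) ** 2 / 2


def test_mw_empty_sample_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def test_mw_order_invariance(rng):
    x, y = rng.normal(size=30), rng.normal(1.0, 1.0, size=25)
    base = mann_whitney(x, y)
    perm = mann_whitney(rng.permutation(x), rng.permutation(y))
    assert base.p_value == pytest.approx(perm.p_value)


def test_mw_shift_power():
    """One-SD shift at n=50 per arm is detected almost always."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 400
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(1.0, 1.0, 50)
        hits += mann_whitney(x, y).p_value < 0.05
    assert hits / reps > 0.9


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def test_friedman_all_tied_is_zero():
    res = friedman([[2.0, 2.0, 2.0]] * 4)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_friedman_strictly_increasing_rows():
    res = friedman([[1, 2, 3], [4, 5, 6], [1, 3, 9]])
    assert res.statistic == pytest.approx(6.0)
    assert res.df == 2


def test_friedman_monotone_invariance(rng):
    m = rng.normal(size=(12, 3))
    res1 = friedman(m)
    res2 = friedman(np.exp(m))  # strictly monotone transform per cell
    assert res1.statistic == pytest.approx(res2.statistic)


def test_friedman_matches_scipy(rng):
    m = rng.integers(0, 5, size=(15, 4)).astype(float)  # ties included
    ours = friedman(m)
    ref = sps.friedmanchisquare(*m.T)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_friedman_errors():
    with pytest.raises(ValueError, match="missing"):
        friedman([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError):
        friedman([[1.0, 2.0]])


def test_friedman_two_conditions_supported():
    res = friedman([[1.0, 2.0], [1.0, 3.0], [2.0, 5.0], [0.0, 1.0]])
    assert res.df == 1
    assert res.statistic > 0


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, r",
    [
        ((1, 2, 3, 4), (1, 2, 3, 4), 1.0),
        ((1, 2, 3, 4), (-1, -2, -3, -4), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
    ],
)
def test_pearson_values(x, y, r):
    assert pearson_r(x, y).statistic == pytest.approx(r)


def test_pearson_constant_errors():
    with pytest.raises(ValueError, match="constant"):
        pearson_r([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# 2x2 odds ratio
# ---------------------------------------------------------------------------

def test_or_hand_values():
    assert two_by_two_or(TwoByTwo(10, 5, 5, 10)).statistic == pytest.approx(4.0)
    assert two_by_two_or(TwoByTwo(7, 7, 7, 7)).statistic == pytest.approx(1.0)


def test_or_haldane_correction():
    res = two_by_two_or(TwoByTwo(0, 8, 4, 12))
    expected = (0.5 * 12.5) / (8.5 * 4.5)
    assert res.statistic == pytest.approx(expected)
    assert res.extras["continuity_corrected"]


def test_or_zero_margin_undefined():
    with pytest.raises(ValueError, match="margin"):
        two_by_two_or(TwoByTwo(0, 0, 3, 4))


def test_or_ci_brackets_or():
    res = two_by_two_or(TwoByTwo(20, 10, 8, 25))
    row = res.coef_table[0]
    assert row.ci_low <= row.odds_ratio <= row.ci_high


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def test_logistic_matches_2x2_odds_ratio(rng):
    """A single binary covariate reduces to the sample 2x2 odds ratio."""
    x = rng.integers(0, 2, 400)
    y = (rng.random(400) < sps.norm.cdf(-0.4 + 1.1 * x)).astype(int)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    table_or = two_by_two_or(TwoByTwo(a, b, c, d)).statistic
    fit = logistic_fit(x[:, None], y, names=["exposure"])
    assert fit.coef("exposure").odds_ratio == pytest.approx(table_or, abs=1e-6)


def test_logistic_constant_covariate_named():
    X = np.column_stack([np.zeros(50), np.random.default_rng(0).normal(size=50)])
    y = np.tile([0, 1], 25)
    with pytest.raises(ValueError, match="flat"):
        logistic_fit(X, y, names=["flat", "ok"])


def test_logistic_rank_deficiency():
    rng = np.random.default_rng(1)
    x = rng.normal(size=60)
    X = np.column_stack([x, 2.0 * x])
    y = rng.integers(0, 2, 60)
    with pytest.raises(ValueError, match="rank"):
        logistic_fit(X, y)


def test_logistic_perfect_separation_named():
    x = np.concatenate([np.zeros(20), np.ones(20)])
    y = x.astype(int)
    with pytest.raises(SeparationError, match="sep"):
        logistic_fit(x[:, None], y, names=["sep"])


def test_logistic_or_recovery_one_replicate(rng):
    x = rng.integers(0, 2, 2000)
    eta = -1.8 + np.log(6.5) * x
    y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = logistic_fit(x[:, None], y, names=["low_t"])
    row = fit.coef("low_t")
    assert abs(row.estimate - np.log(6.5)) < 3 * row.se
    assert row.ci_low <= row.odds_ratio <= row.ci_high
    assert fit.extras["converged"]


def test_logistic_summary_table():
    rng = np.random.default_rng(2)
    x = rng.normal(size=300)
    y = (rng.random(300) < sps.norm.cdf(x)).astype(int)
    fit = logistic_fit(x[:, None], y, names=["t"])
    text = fit.summary()
    assert "OR" in text and "95% CI" in text and "t" in text


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def test_group_comparison_shape(small_cohort):
    import pandas as pd
    from pcosmet.cohort import baseline_frame

    cohort, _ = small_cohort
    frame = baseline_frame(cohort, "m0")
    completer = pd.Series(
        {r.patient_id: r.status == "completed" for r in cohort}
    )
    table = group_comparison(frame, completer, variables=["t", "fai", "bmi"])
    assert list(table.index) == ["t", "fai", "bmi"]
    assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()
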