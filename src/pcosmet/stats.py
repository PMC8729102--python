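"""Classical inference stages: rank tests, logistic drop-out model, 2×2 risk.

Wraps the field-standard routines (scipy rank tests, statsmodels maximum-
likelihood logistic regression) behind a uniform :class:`FitResult` results
object with odds ratios, Wald 95 % confidence intervals and two-sided
p-values.  The Friedman statistic is computed directly from within-subject
ranks with the usual tie correction so that two-condition designs are
supported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "CoefRow",
    "FitResult",
    "TwoByTwo",
    "SeparationError",
    "mann_whitney",
    "friedman",
    "logistic_fit",
    "two_by_two_or",
    "pearson_r",
    "group_comparison",
]

Z_975 = float(sps.norm.ppf(0.975))


class SeparationError(ValueError):
    """The logistic likelihood is unbounded (perfectly separating covariate)."""


@dataclass(frozen=True)
class CoefRow:
    """One covariate's estimate on the log-odds scale with its Wald interval."""

    name: str
    estimate: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class FitResult:
    """Uniform container for a test or model fit."""

    method: str
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    df: Optional[float] = None
    n: Optional[int] = None
    coef_table: Optional[list[CoefRow]] = None
    extras: dict = field(default_factory=dict)

    def coef(self, name: str) -> CoefRow:
        for row in self.coef_table or []:
            if row.name == name:
                return row
        raise KeyError(name)

    def summary(self) -> str:
        lines = [self.method, "=" * max(44, len(self.method))]
        if self.statistic is not None:
            stat = f"statistic = {self.statistic:.4f}"
            if self.df is not None:
                stat += f"  (df = {self.df:g})"
            lines.append(stat)
        if self.p_value is not None:
            lines.append(f"p-value   = {self.p_value:.4g}   (two-sided)")
        if self.n is not None:
            lines.append(f"n         = {self.n}")
        if self.coef_table:
            lines.append("")
            lines.append(f"{'variable':<14}{'OR':>10}{'95% CI':>22}{'P value':>10}")
            for row in self.coef_table:
                ci = f"{row.ci_low:.3f}-{row.ci_high:.3f}"
                lines.append(
                    f"{row.name:<14}{row.odds_ratio:>10.3f}{ci:>22}{row.p_value:>10.3f}"
                )
        for key, val in self.extras.items():
            if isinstance(val, float):
                lines.append(f"{key} = {val:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "n": self.n,
        }
        if self.coef_table:
            out["coefficients"] = [
                {
                    "name": r.name, "estimate": r.estimate, "se": r.se,
                    "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p_value": r.p_value,
                }
                for r in self.coef_table
            ]
        out.update({k: v for k, v in self.extras.items()})
        return out


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> FitResult:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration when n1 + n2 ≤ 10 and there are no ties, the
    tie-corrected normal approximation otherwise.  The statistic is the U of
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) + len(y) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return FitResult(
        method=f"Mann-Whitney U ({method})",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=len(x) + len(y),
        extras={"n1": len(x), "n2": len(y)},
    )


def friedman(matrix) -> FitResult:
    """Friedman two-way rank ANOVA for correlated samples (subjects × conditions).

    Tie-corrected chi-square statistic with k − 1 degrees of freedom; an
    all-tied design yields statistic 0 and p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed; delete listwise first")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        statistic = 0.0
    else:
        statistic = uncorrected / correction
    statistic = max(statistic, 0.0)
    df = k - 1
    p = float(sps.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return FitResult(
        method="Friedman rank ANOVA", statistic=float(statistic),
        p_value=p, df=df, n=n,
    )


def pearson_r(x, y) -> FitResult:
    """Pearson product-moment correlation with a t-approximation p-value.

    With one binary input this is the point-biserial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = sps.pearsonr(x, y)
    return FitResult(
        method="Pearson correlation", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=len(x),
    )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def logistic_fit(X, y, names: Optional[Sequence[str]] = None) -> FitResult:
    """Multivariate logistic regression by maximum likelihood (IRLS/Newton).

    Returns per-covariate log-odds estimates, odds ratios with Wald 95 %
    confidence intervals, and two-sided Wald p-values.  Raises
    :class:`SeparationError` on perfect separation and ``ValueError`` on
    constant or collinear covariates, naming the offender.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than covariates")
    if not np.isin(np.unique(y), (0.0, 1.0)).all() or len(np.unique(y)) < 2:
        raise ValueError("y must be binary with both classes present")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"covariate {names[j]!r} is constant; drop it")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")

    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-8)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            j = int(np.argmax([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(p)]))
            raise SeparationError(
                f"perfect separation; covariate {names[j]!r} separates the classes"
            ) from exc
    params = fit.params
    bse = fit.bse
    if not np.all(np.isfinite(bse)) or np.max(np.abs(params[1:])) > 50:
        j = int(np.argmax(np.abs(params[1:])))
        raise SeparationError(
            f"perfect separation; covariate {names[j]!r} separates the classes"
        )
    rows = []
    for j, name in enumerate(["intercept"] + list(names)):
        est, se = float(params[j]), float(bse[j])
        rows.append(
            CoefRow(
                name=name,
                estimate=est,
                se=se,
                odds_ratio=math.exp(est),
                ci_low=math.exp(est - Z_975 * se),
                ci_high=math.exp(est + Z_975 * se),
                p_value=float(2 * sps.norm.sf(abs(est) / se)),
            )
        )
    return FitResult(
        method="Multivariate logistic regression (ML, Wald CIs)",
        statistic=float(fit.llr),
        p_value=float(fit.llr_pvalue),
        df=float(fit.df_model),
        n=n,
        coef_table=rows,
        extras={"log_likelihood": float(fit.llf), "converged": bool(fit.mle_retvals["converged"])},
    )


# ---------------------------------------------------------------------------
# 2×2 odds ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × event counts: a = exposed events, b = exposed non-events,
    c = unexposed events, d = unexposed non-events."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")


def two_by_two_or(t: TwoByTwo) -> FitResult:
    """Sample odds ratio (a·d)/(b·c) with Woolf (log) 95 % CI.

    When any cell is zero the Haldane–Anscombe 0.5 continuity correction is
    applied to every cell.  A zero row or column leaves the OR undefined.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a zero margin leaves the odds ratio undefined")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    p = float(2 * sps.norm.sf(abs(log_or) / se))
    return FitResult(
        method="2x2 odds ratio (Woolf CI)",
        statistic=float(or_),
        p_value=p,
        n=int(t.a + t.b + t.c + t.d),
        coef_table=[
            CoefRow(
                name="exposure",
                estimate=log_or,
                se=se,
                odds_ratio=float(or_),
                ci_low=math.exp(log_or - Z_975 * se),
                ci_high=math.exp(log_or + Z_975 * se),
                p_value=p,
            )
        ],
        extras={"continuity_corrected": corrected},
    )


# ---------------------------------------------------------------------------
# Group comparison table
# ---------------------------------------------------------------------------

def group_comparison(
    frame: pd.DataFrame, group: pd.Series, variables: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Baseline mean ± SD per group with Mann–Whitney p-values.

    ``group`` is a boolean series aligned with ``frame`` (True = first group,
    e.g. completers).  Mirrors the usual completers-vs-discontinued table.
    """
    if variables is None:
        variables = [c for c in frame.columns if frame[c].dtype.kind in "fi"]
    group = group.reindex(frame.index)
    rows = []
    for var in variables:
        g1 = frame.loc[group.astype(bool), var].dropna()
        g0 = frame.loc[~group.astype(bool), var].dropna()
        if len(g1) == 0 or len(g0) == 0:
            continue
        res = mann_whitney(g1, g0)
        rows.append(
            {
                "variable": var,
                "group1_mean": g1.mean(), "group1_sd": g1.std(ddof=1),
                "group2_mean": g0.mean(), "group2_sd": g0.std(ddof=1),
                "p_value": res.p_value,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["group1_mean", "group1_sd", "group2_mean", "group2_sd", "p_value"]
        )
    return pd.DataFrame(rows).set_index("variable")
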