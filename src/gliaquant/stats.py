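"""Cohort-level statistics: cumulative IOP, normality-gated two-group
tests, one-way ANOVA with Tukey-Kramer post hoc comparisons, and least
squares regression with pointwise confidence bands.

The two-group test mirrors the gated protocol: each group is checked with
Shapiro-Wilk at alpha = 0.05 and the Wilcoxon rank-sum test replaces the
t-test when *any* group fails (or is too small for the gate).  The exact
Wilcoxon branch enumerates all assignments of pooled ranks for combined
n <= 20, which handles ties correctly; larger samples use the
tie-corrected normal approximation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "IOPSeries",
    "TestResult",
    "LinRegResult",
    "cumulative_iop",
    "wilcoxon_ranksum",
    "two_group_test",
    "anova_tukey",
    "linreg_ci",
]

EXACT_WILCOXON_MAX_N = 20


@dataclass
class IOPSeries:
    """Intraocular pressure measurements over time for one eye/group."""

    day: np.ndarray
    iop: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.iop = np.asarray(self.iop, dtype=float)
        if self.day.shape != self.iop.shape:
            raise ValueError("day and iop must have the same length")
        if (self.iop <= 0).any():
            raise ValueError("iop values must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.day, "iop": self.iop, "label": self.label})


@dataclass
class TestResult:
    method: str  # t | wilcoxon | anova
    statistic: float
    p: float
    pairwise: pd.DataFrame | None = None
    normality_p: dict[str, float] | None = None
    exact: bool | None = None

    def to_json(self) -> str:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "normality_p": self.normality_p,
            "exact": self.exact,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return json.dumps(d)


# ---------------------------------------------------------------------------


def cumulative_iop(series: IOPSeries, baseline: float | None = None) -> float:
    """Cumulative IOP: trapezoidal area under the IOP curve (mmHg*days).

    By default the raw area is reported; ``baseline`` subtracts a constant
    before integration (area above baseline).
    """
    if series.day.size < 2:
        raise ValueError("need at least 2 time points")
    if not (np.diff(series.day) > 0).all():
        raise ValueError("days must be strictly increasing")
    iop = series.iop if baseline is None else series.iop - baseline
    return float(np.trapezoid(iop, series.day))


# ---------------------------------------------------------------------------
# two-group test


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum p by enumerating all C(n, n_a)
    assignments of the pooled (mid-)ranks.  Returns (rank sum of a, p)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, na = pooled.size, a.size
    w_obs = ranks[:na].sum()
    idx = np.fromiter(
        (i for comb in combinations(range(n), na) for i in comb),
        dtype=np.intp,
    ).reshape(-1, na)
    sums = ranks[idx].sum(axis=1)
    total = sums.size
    tol = 1e-9
    p_lo = np.count_nonzero(sums <= w_obs + tol) / total
    p_hi = np.count_nonzero(sums >= w_obs - tol) / total
    return float(w_obs), min(1.0, 2.0 * min(p_lo, p_hi))


def wilcoxon_ranksum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact permutation null for combined n <= 20 (ties handled via
    mid-ranks); tie-corrected normal approximation with continuity
    correction above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult("wilcoxon", float(sps.rankdata(pooled)[: a.size].sum()), 1.0,
                          exact=True)
    if pooled.size <= EXACT_WILCOXON_MAX_N:
        w, p = _exact_ranksum_p(a, b)
        return TestResult("wilcoxon", w, p, exact=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return TestResult("wilcoxon", w, float(res.pvalue), exact=False)


def two_group_test(a, b, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk-gated comparison of two independent samples.

    Both groups are tested for normality at ``alpha``; the Wilcoxon
    rank-sum test is used if any group fails the gate or is too small for
    it (n < 3), otherwise a two-sided two-sample t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        res = wilcoxon_ranksum(a, b)
        res.p = 1.0
        return res

    normality: dict[str, float] = {}
    use_nonparametric = False
    for name, x in (("a", a), ("b", b)):
        if x.size < 3:
            use_nonparametric = True
            continue
        if np.ptp(x) == 0:
            normality[name] = 0.0  # degenerate: certainly not Gaussian
            use_nonparametric = True
            continue
        p = float(sps.shapiro(x).pvalue)
        normality[name] = p
        if p < alpha:
            use_nonparametric = True

    if use_nonparametric:
        res = wilcoxon_ranksum(a, b)
        res.normality_p = normality or None
        return res
    t = sps.ttest_ind(a, b)
    return TestResult("t", float(t.statistic), float(t.pvalue), normality_p=normality)


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer


def anova_tukey(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> TestResult:
    """One-way ANOVA with Tukey-Kramer pairwise post hoc comparisons.

    Handles unequal group sizes (Kramer's adjustment via the studentized
    range distribution).  Requires >= 3 groups with >= 2 observations each.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least 3 groups (use two_group_test for 2)")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = [
            {"group_a": labels[i], "group_b": labels[j], "diff": 0.0, "p_adj": 1.0,
             "ci_lo": 0.0, "ci_hi": 0.0}
            for i, j in combinations(range(len(arrays)), 2)
        ]
        return TestResult("anova", 0.0, 1.0, pairwise=pd.DataFrame(pairs))

    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    ci = hsd.confidence_interval(0.95)
    pairs = []
    for i, j in combinations(range(len(arrays)), 2):
        pairs.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adj": float(hsd.pvalue[i, j]),
                "ci_lo": float(ci.low[i, j]),
                "ci_hi": float(ci.high[i, j]),
            }
        )
    return TestResult("anova", float(f), float(p), pairwise=pd.DataFrame(pairs))


# ---------------------------------------------------------------------------
# least squares regression with confidence band


@dataclass
class LinRegResult:
    slope: float
    intercept: float
    r_squared: float
    band: pd.DataFrame = field(repr=False)  # x, fit, ci_lo, ci_hi


def linreg_ci(
    x, y, x_eval=None, alpha: float = 0.05
) -> LinRegResult:
    """Ordinary least squares with a t-based pointwise confidence band for
    the conditional mean."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if x_eval is None:
        x_eval = np.sort(x)
    x_eval = np.asarray(x_eval, dtype=float)
    exog = np.column_stack([np.ones_like(x_eval), x_eval])
    pred = fit.get_prediction(exog)
    ci = pred.conf_int(alpha=alpha)
    band = pd.DataFrame(
        {
            "x": x_eval,
            "fit": pred.predicted_mean,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
        }
    )
    return LinRegResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        band=band,
    )
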