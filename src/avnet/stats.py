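"""Statistical procedures used in the group and error analyses.

Thin, validated wrappers around scipy.stats with the exact conventions this
analysis needs: pooled-variance (Student) independent t-tests with a fixed
one-tailed direction (group x hypothesised larger than group y), paired t on
differences, product-moment correlation, and Pearson chi-square tests with
no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "StatsError", "t_independent", "t_paired",
           "pearson_r", "chisq_gof", "chisq_2x2"]


class StatsError(ValueError):
    """Degenerate input for a statistical test (zero variance, empty cell)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    tails: str = "two"          # "one" | "two"
    n: int | None = None
    kind: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def summary(self) -> str:
        tail = "one-tailed" if self.tails == "one" else "two-tailed"
        return (f"{self.kind}: statistic = {self.statistic:.4g}, "
                f"df = {self.df:g}, p = {self.p_value:.4g} ({tail})")


def _as_array(x: Sequence[float], name: str, min_len: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < min_len:
        raise StatsError(f"{name} must be 1-d with at least {min_len} values")
    return arr


def t_independent(x: Sequence[float], y: Sequence[float],
                  tails: str = "one") -> TestResult:
    """Pooled-variance Student t-test, df = n1 + n2 - 2.

    One-tailed p is for the a-priori direction mean(x) > mean(y); pass the
    hypothesised-larger group as ``x``.
    """
    x, y = _as_array(x, "x", 2), _as_array(y, "y", 2)
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        raise StatsError("zero pooled variance")
    alternative = "greater" if tails == "one" else "two-sided"
    res = sps.ttest_ind(x, y, equal_var=True, alternative=alternative)
    return TestResult(statistic=float(res.statistic),
                      df=float(len(x) + len(y) - 2),
                      p_value=float(res.pvalue), tails=tails,
                      n=len(x) + len(y), kind="independent t")


def t_paired(x: Sequence[float], y: Sequence[float],
             tails: str = "two") -> TestResult:
    """Paired t-test on the per-pair differences, df = n - 1."""
    x, y = _as_array(x, "x", 2), _as_array(y, "y", 2)
    if len(x) != len(y):
        raise StatsError("paired samples must have equal length")
    diffs = x - y
    if np.var(diffs, ddof=1) == 0.0:
        raise StatsError("zero variance of paired differences")
    alternative = "greater" if tails == "one" else "two-sided"
    res = sps.ttest_rel(x, y, alternative=alternative)
    return TestResult(statistic=float(res.statistic), df=float(len(x) - 1),
                      p_value=float(res.pvalue), tails=tails, n=len(x),
                      kind="paired t")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson product-moment correlation with its two-tailed p."""
    x, y = _as_array(x, "x", 3), _as_array(y, "y", 3)
    if len(x) != len(y):
        raise StatsError("samples must have equal length")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise StatsError("constant input has no defined correlation")
    res = sps.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), df=float(len(x) - 2),
                      p_value=float(res.pvalue), tails="two", n=len(x),
                      kind="pearson r")


def chisq_gof(observed: Sequence[float],
              expected: Sequence[float] | str = "equal") -> TestResult:
    """Pearson chi-square goodness of fit, df = k - 1, no continuity
    correction.  ``expected="equal"`` spreads the total evenly."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2 or np.any(obs < 0):
        raise StatsError("observed must be >=2 nonnegative counts")
    if isinstance(expected, str):
        if expected != "equal":
            raise StatsError(f"unknown expected spec {expected!r}")
        exp = np.full_like(obs, obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise StatsError("observed/expected length mismatch")
    if np.any(exp <= 0):
        raise StatsError("expected counts must be positive")
    res = sps.chisquare(obs, exp)
    return TestResult(statistic=float(res.statistic), df=float(len(obs) - 1),
                      p_value=float(res.pvalue), tails="two",
                      n=int(obs.sum()), kind="chi-square gof")


def chisq_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square of independence on a 2x2 table, expecteds from the
    margins, df = 1, no Yates correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise StatsError("table must be 2x2 with nonnegative cells")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise StatsError("zero row or column margin")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult(statistic=float(chi2), df=float(df), p_value=float(p),
                      tails="two", n=int(tab.sum()), kind="chi-square 2x2")
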