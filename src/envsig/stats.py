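"""Shared statistical layer: unpaired Student t, one-way ANOVA, Pearson /
Spearman correlation with a normality gate, and simple least squares.

All tests are two-sided.  The t-test is the pooled-variance (classical
Student) form; a Welch variant is available behind a flag.  No
multiple-testing correction is applied anywhere in the selection path; a
Benjamini-Hochberg helper exists but is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values")
    return a


def t_test_unpaired(x, y, welch: bool = False) -> TestResult:
    """Two-sided two-sample t test (pooled variance unless ``welch``).

    Degenerate case: both groups constant.  Equal constants give t=0, p=1;
    unequal constants are flagged with the p=0 convention.
    """
    x, y = _as1d(x), _as1d(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(x) + len(y) - 2
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, df, "student_t_unpaired", degenerate=True)
        sign = 1.0 if np.mean(x) > np.mean(y) else -1.0
        return TestResult(sign * np.inf, 0.0, df, "student_t_unpaired", degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        df = sps.ttest_ind(x, y, equal_var=False).df
    return TestResult(float(t), float(p), float(df), "welch_t" if welch else "student_t_unpaired")


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA across >=2 groups of >=2 values each."""
    gs = [_as1d(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least 2 values")
    k = len(gs)
    if all(np.var(g, ddof=1) == 0.0 for g in gs):
        means = [float(np.mean(g)) for g in gs]
        if len(set(means)) == 1:
            return TestResult(0.0, 1.0, k - 1, "anova_oneway", degenerate=True)
        return TestResult(np.inf, 0.0, k - 1, "anova_oneway", degenerate=True)
    f, p = sps.f_oneway(*gs)
    return TestResult(float(f), float(p), float(k - 1), "anova_oneway")


def pearson(x, y) -> TestResult:
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), float(len(x) - 2), "pearson")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (Pearson on midranks; ties get midranks)."""
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), float(len(x) - 2), "spearman")


def choose_correlation(x, y, alpha_normality: float = 0.05) -> TestResult:
    """Pearson if both vectors pass Shapiro-Wilk at ``alpha_normality``,
    otherwise Spearman; the chosen method is recorded in the result."""
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    normal = all(sps.shapiro(v).pvalue > alpha_normality for v in (x, y))
    return pearson(x, y) if normal else spearman(x, y)


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    stderr_slope: float
    n: int


def ols_regression(x, y) -> OLSResult:
    """Simple least-squares line with a two-sided t test on the slope."""
    x, y = _as1d(x), _as1d(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = sps.linregress(x, y)
    return OLSResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_slope=float(fit.pvalue),
        stderr_slope=float(fit.stderr),
        n=len(x),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (opt-in; the selection path never uses this)."""
    p = _as1d(p_values)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def row_t_tests(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled-variance t tests per matrix row.

    ``a`` and ``b`` are (rows x samples) for the two groups.  Returns
    ``(t, p, degenerate)``; degenerate rows (zero pooled variance) get t=0,
    p=1 when means are equal and t=+-inf, p=0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    degenerate = sp2 == 0.0
    se = np.sqrt(np.where(degenerate, 1.0, sp2) * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    diff = m1 - m2
    deg_t = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    t = np.where(degenerate, deg_t, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p, degenerate
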