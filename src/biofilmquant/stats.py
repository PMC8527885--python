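"""Statistical machinery for the screening analysis.

2×2 odds ratios with Wald confidence intervals, Fisher's exact test,
Mann-Whitney U, Kruskal-Wallis, Benjamini-Hochberg adjustment, grouped
binomial logistic regression fitted by iteratively reweighted least squares
(IRLS), confusion-matrix metrics and a t test on log-transformed data.

Nonparametric tests delegate to scipy.stats and the multiple-testing
step-up to statsmodels; the IRLS fitter is implemented here and
cross-checked against statsmodels GLM in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Contingency2x2",
    "ORResult",
    "TestResult",
    "LogisticFit",
    "odds_ratio_2x2",
    "fisher_exact",
    "mann_whitney_u",
    "kruskal_wallis",
    "bh_adjust",
    "fit_grouped_logistic",
    "confusion_metrics",
    "log_t_test",
]


@dataclass(frozen=True)
class Contingency2x2:
    """Exposure × outcome counts.

    a, b: outcome-positive / -negative in the exposed (e.g. disease) group;
    c, d: outcome-positive / -negative in the reference group.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    continuity_corrected: bool = False


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def odds_ratio_2x2(t: Contingency2x2, ci_level: float = 0.95) -> ORResult:
    """Sample odds ratio (a·d)/(b·c) with a Wald CI on the log scale.

    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells (flagged in the result). A table with an entirely empty row
    or column has no defined odds ratio and raises.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        raise ValueError("odds ratio undefined: empty table margin")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return ORResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        ci_level=ci_level,
        continuity_corrected=corrected,
    )


def fisher_exact(t: Contingency2x2, rule: str = "minlike") -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    ``rule='minlike'`` (default) sums the hypergeometric probabilities of
    all tables with fixed margins whose probability does not exceed that of
    the observed table. ``rule='doubling'`` doubles the smaller one-sided
    tail, clipped at 1.
    """
    if rule == "minlike":
        res = sps.fisher_exact(t.table, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "Fisher exact (minlike)")
    if rule == "doubling":
        less = sps.fisher_exact(t.table, alternative="less").pvalue
        greater = sps.fisher_exact(t.table, alternative="greater").pvalue
        p = min(1.0, 2 * min(less, greater))
        stat = sps.fisher_exact(t.table).statistic
        return TestResult(float(stat), float(p), "Fisher exact (doubling)")
    raise ValueError(f"unknown rule {rule!r}")


def mann_whitney_u(x, y, sidedness: str = "two-sided") -> TestResult:
    """Mann-Whitney U with midranks.

    Exact enumeration when the pooled sample has at most 16 observations
    and no ties; otherwise the normal approximation with tie and continuity
    corrections. The statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size + y.size <= 16 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=sidedness, method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"Mann-Whitney U ({method})", sidedness)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k−1 df).

    A degenerate input where every value is identical gives H = 0, p = 1.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) \
            and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "Kruskal-Wallis")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "Kruskal-Wallis")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge or the data are separated."""


@dataclass(frozen=True)
class LogisticFit:
    """Grouped-binomial logistic regression fit."""

    coef: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_iter: int
    ci_level: float = 0.95


def fit_grouped_logistic(X, successes, totals, ci_level: float = 0.95,
                         tol: float = 1e-8,
                         max_iter: int = 50) -> LogisticFit:
    """Maximum-likelihood logistic regression on grouped binomial data.

    Fits successes_i ~ Binomial(totals_i, expit(X_i · β)) by iteratively
    reweighted least squares. Reports exp(β) with Wald confidence
    intervals. Raises :class:`ConvergenceError` on non-convergence or
    (quasi-)separation, detected as diverging coefficients or vanishing
    working weights.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    s = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(s < 0) or np.any(n < s):
        raise ValueError("need 0 <= successes <= totals")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = sps.logistic.cdf(eta)
        w = n * mu * (1 - mu)
        if np.any(w < 1e-10) or np.any(np.abs(beta) > 30):
            raise ConvergenceError(
                "separation suspected: fitted probabilities at the boundary "
                f"or |coefficient| > 30 at iteration {it}")
        z = eta + (s - n * mu) / w
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} "
                               "iterations")

    eta = X @ beta
    mu = sps.logistic.cdf(eta)
    w = n * mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    zcrit = sps.norm.ppf(0.5 + ci_level / 2)
    return LogisticFit(
        coef=beta, se=se, odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - zcrit * se), ci_high=np.exp(beta + zcrit * se),
        n_iter=it, ci_level=ci_level,
    )


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from a 2×2 confusion table.

    Zero denominators yield NaN for the affected metric rather than an
    exception.
    """
    for v in (tp, fn, fp, tn):
        if v < 0 or v != int(v):
            raise ValueError("counts must be nonnegative integers")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("empty confusion table")
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": tp / (tp + fn) if tp + fn > 0 else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp > 0 else float("nan"),
    }


def log_t_test(x, y, sidedness: str = "two-sided") -> TestResult:
    """Two-sample t test on log-transformed (strictly positive) data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log transform requires strictly positive values")
    res = sps.ttest_ind(np.log(x), np.log(y), alternative=sidedness)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "t test on log-transformed data", sidedness)
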