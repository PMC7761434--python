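"""Statistical comparison of cross-validation accuracy populations.

The validation chain applied to two populations of CV accuracies:

1. Lilliefors test of normality on each population (Kolmogorov-Smirnov
   statistic against a normal with estimated mean/SD, table-interpolated p);
2. homogeneity of variance across the two populations (Bartlett's test by
   default, Levene selectable for robustness to non-normality);
3. pooled-variance two-sample t-test

       t = (mean1 - mean2) / sqrt( s_p^2 * (1/n1 + 1/n2) ),
       s_p^2 = ((n1-1)*s1^2 + (n2-1)*s2^2) / (n1 + n2 - 2)

   with n1 + n2 - 2 degrees of freedom, two-sided by default.

All tests return a :class:`TestResult` whose ``reject`` flag applies the
decision rule p <= alpha (alpha = 0.05 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

__all__ = [
    "TestResult",
    "lilliefors_normality",
    "equal_variance_test",
    "two_sample_t",
    "pooled_mean",
    "compare_accuracies",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test: statistic, p-value and decision."""

    name: str
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def reject(self) -> bool:
        """True when the null is rejected at level alpha (p <= alpha)."""
        return self.p_value <= self.alpha


def _sample(x, name, min_size):
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_size:
        raise ValueError(f"{name} needs at least {min_size} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def lilliefors_normality(sample, alpha: float = 0.05) -> TestResult:
    """Lilliefors (KS with estimated parameters) test of normality."""
    x = _sample(sample, "sample", 4)
    if x.std() == 0.0:
        raise ValueError("sample is constant: normality test is degenerate")
    stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return TestResult("lilliefors", float(stat), float(p), alpha)


def equal_variance_test(sample1, sample2, alpha: float = 0.05,
                        method: str = "bartlett") -> TestResult:
    """Homogeneity of variance between two groups (Bartlett or Levene)."""
    x1 = _sample(sample1, "sample1", 2)
    x2 = _sample(sample2, "sample2", 2)
    if x1.std() == 0.0 and x2.std() == 0.0:
        raise ValueError("both groups have zero variance: test is degenerate")
    if method == "bartlett":
        stat, p = sps.bartlett(x1, x2)
    elif method == "levene":
        stat, p = sps.levene(x1, x2)
    else:
        raise ValueError(f"method must be 'bartlett' or 'levene', got {method!r}")
    return TestResult(method, float(stat), float(p), alpha)


def two_sample_t(sample1, sample2, alpha: float = 0.05,
                 alternative: str = "two-sided") -> TestResult:
    """Pooled-variance two-sample t-test.

    ``alternative`` is ``"two-sided"`` (default), ``"greater"`` (mean1 >
    mean2) or ``"less"``. Degenerate zero-pooled-variance inputs yield t = 0,
    p = 1 for equal means and t = +/-inf, p -> 0 otherwise.
    """
    x1 = _sample(sample1, "sample1", 2)
    x2 = _sample(sample2, "sample2", 2)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    s2p = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    diff = float(x1.mean() - x2.mean())
    se = math.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df) if math.isfinite(t) else (1.0 if t == 0 else 0.0)
    elif alternative == "greater":
        p = sps.t.sf(t, df) if math.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        p = sps.t.cdf(t, df) if math.isfinite(t) else (0.0 if t < 0 else 1.0)
    return TestResult(f"t-test ({alternative})", float(t), float(p), alpha)


def pooled_mean(sample1, sample2) -> float:
    """Mean of the two groups pooled into one sample."""
    x1 = _sample(sample1, "sample1", 1)
    x2 = _sample(sample2, "sample2", 1)
    return float(np.concatenate([x1, x2]).mean())


def compare_accuracies(sample1, sample2, alpha: float = 0.05,
                       variance_method: str = "bartlett",
                       alternative: str = "two-sided") -> dict:
    """Full comparison report for two CV accuracy populations.

    Runs the Lilliefors test on each population, the equal-variance test and
    the pooled two-sample t-test, and summarises counts, means and the pooled
    mean in a JSON-serialisable dict.
    """
    x1 = _sample(sample1, "sample1", 4)
    x2 = _sample(sample2, "sample2", 4)
    lil1 = lilliefors_normality(x1, alpha)
    lil2 = lilliefors_normality(x2, alpha)
    var = equal_variance_test(x1, x2, alpha, method=variance_method)
    tt = two_sample_t(x1, x2, alpha, alternative=alternative)

    def _res(r: TestResult) -> dict:
        return {"statistic": r.statistic, "p_value": r.p_value,
                "h": int(r.reject), "alpha": r.alpha}

    return {
        "population1": {"count": int(x1.size), "mean": float(x1.mean()),
                        "sd": float(x1.std(ddof=1)), "lilliefors": _res(lil1)},
        "population2": {"count": int(x2.size), "mean": float(x2.mean()),
                        "sd": float(x2.std(ddof=1)), "lilliefors": _res(lil2)},
        "pooled": {"count": int(x1.size + x2.size),
                   "mean": pooled_mean(x1, x2)},
        "variance": _res(var),
        "t_test": {**_res(tt), "alternative": alternative,
                   "df": int(x1.size + x2.size - 2)},
    }
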