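"""Exact and adjusted test statistics shared by every pipeline stage.

Three primitives recur throughout the pipeline: the two-sided Fisher exact
test on 2x2 contingency tables (splicing calls, kinase-downstream and GO
enrichment), Welch's unequal-variance t-test on log ratios (differential
phosphorylation), and the Benjamini-Hochberg step-up adjustment that turns
each family of p-values into q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["TestResult", "fisher_exact_two_sided", "welch_test", "benjamini_hochberg"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the odds ratio for Fisher's test and the t statistic for
    Welch's test; ``df`` is only meaningful for Welch (NaN otherwise).
    """

    statistic: float
    p_value: float
    df: float = math.nan


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    Uses the probability rule: the p-value is the sum of hypergeometric
    probabilities of every table with the same margins whose probability does
    not exceed that of the observed table. The reported statistic is the
    sample odds ratio (a*d)/(b*c), with ``inf`` when b*c == 0.

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Non-negative integer counts; rows are groups, columns are outcome
        classes (e.g. skipping vs inclusion reads).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.all(np.isfinite(t)):
        raise ValueError("table entries must be finite")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    if np.any(t != np.floor(t)):
        raise ValueError("table entries must be integers")
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    a, b = t[0]
    c, d = t[1]
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    p = float(_sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
    return TestResult(statistic=float(odds), p_value=min(p, 1.0))


def welch_test(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances, two-sided).

    Degenerate inputs are mapped to documented sentinels so that pipeline
    stages can filter rather than crash: if both groups have zero variance
    and equal means the result is ``t=0, p=1``; zero variance in both groups
    with unequal means yields ``t=+/-inf, p=0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("observations must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(nx + ny - 2)
        if mx == my:
            return TestResult(statistic=0.0, p_value=1.0, df=df)
        return TestResult(statistic=math.copysign(math.inf, mx - my), p_value=0.0, df=df)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(p, 1.0), df=float(df))


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j>=i} p_(j) * n / j`` over the ascending order statistics,
    clipped at 1 and mapped back to the input order. Ties are broken by a
    stable sort, so the result is equivariant under permutation of the input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q
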