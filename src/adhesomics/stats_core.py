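"""Shared statistical primitives for the pipeline stages.

Variance-gated two-sample t-tests (Student vs Welch selected by an F-test
on the variance ratio), Benjamini-Hochberg adjustment, one-sided
hypergeometric over-representation, Spearman rank correlation and the
qPCR delta-delta-Ct fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestVariant",
    "TestResult",
    "EnrichmentRecord",
    "variance_gated_t",
    "bh_adjust",
    "hypergeom_ora",
    "log_hypergeom_tail",
    "spearman_rho",
    "ddct_fold_change",
]


class TestVariant(str, Enum):
    STUDENT = "student"
    WELCH = "welch"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided two-sample t-test."""

    statistic: float
    df: float
    p: float
    variant: TestVariant


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric over-representation result for one gene set.

    ``overlap`` (x) of the ``query_size`` (n) query identifiers fall in a
    set annotating ``set_size_in_universe`` (K) of the ``universe`` (N)
    identifiers. ``enrichment_ratio`` is (x/n)/(K/N).
    """

    set_id: str
    overlap: int
    set_size_in_universe: int
    query_size: int
    universe: int
    p: float
    q: float | None
    enrichment_ratio: float


def variance_gated_t(x, y, alpha_f: float = 0.05) -> TestResult:
    """Two-sided t-test choosing pooled (Student) or Satterthwaite (Welch) df.

    A two-sided F-test on the sample-variance ratio at level ``alpha_f``
    gates the choice: unequal variances (F-test p < alpha_f) select
    Welch's test, otherwise the pooled-variance Student's test is used.

    Degenerate samples with zero variance in both groups and equal means
    return statistic 0 and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")

    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(x.size + y.size - 2), 1.0, TestVariant.STUDENT)
        # infinite separation relative to zero spread
        stat = math.inf if x.mean() > y.mean() else -math.inf
        return TestResult(stat, float(x.size + y.size - 2), 0.0, TestVariant.STUDENT)

    # two-sided F-test on the variance ratio
    f = vx / vy if vy > 0 else math.inf
    dfx, dfy = x.size - 1, y.size - 1
    cdf = stats.f.cdf(f, dfx, dfy)
    p_f = 2.0 * min(cdf, 1.0 - cdf)
    equal_var = p_f >= alpha_f
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    variant = TestVariant.STUDENT if equal_var else TestVariant.WELCH
    p = float(res.pvalue)
    if not np.isfinite(p):  # identical constant-free corner cases
        p = 1.0
    return TestResult(float(res.statistic), float(res.df), max(p, np.nextafter(0, 1)), variant)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_binom(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """ln P(X >= x) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if not (0 <= x <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts x={x}, K={K}, n={n}, N={N}")
    hi = min(K, n)
    lo = max(x, n - (N - K))  # below this the complement cannot supply n-k draws
    ks = np.arange(lo, hi + 1)
    if ks.size == 0:
        return -math.inf
    log_terms = np.array(
        [_log_binom(K, k) + _log_binom(N - K, n - k) for k in ks]
    ) - _log_binom(N, n)
    return min(float(logsumexp(log_terms)), 0.0)


def hypergeom_ora(x: int, K: int, n: int, N: int) -> EnrichmentRecord:
    """Upper-tail hypergeometric test P(X >= x) with enrichment ratio.

    The tail is summed in log space (log-gamma binomials) so that
    universes of ~2e4 identifiers do not overflow.
    """
    if not (0 <= x <= n <= N and x <= K <= N):
        raise ValueError(f"inconsistent counts x={x}, K={K}, n={n}, N={N}")
    if x > min(K, n):
        raise ValueError("overlap exceeds min(set size, query size)")
    lt = log_hypergeom_tail(x, K, n, N)
    p = 0.0 if lt == -math.inf else min(float(np.exp(lt)), 1.0)
    ratio = float("nan")
    if K > 0 and n > 0:
        ratio = (x / n) / (K / N)
    return EnrichmentRecord(
        set_id="",
        overlap=int(x),
        set_size_in_universe=int(K),
        query_size=int(n),
        universe=int(N),
        p=p,
        q=None,
        enrichment_ratio=ratio,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson of mid-ranks; ties averaged).

    Returns NaN for constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def ddct_fold_change(
    ct_target_s: float, ct_ref_s: float, ct_target_c: float, ct_ref_c: float
) -> float:
    """Relative expression 2^(-ddCt) of sample vs calibrator, reference-normalised."""
    for v in (ct_target_s, ct_ref_s, ct_target_c, ct_ref_c):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_s - ct_ref_s) - (ct_target_c - ct_ref_c)
    return 2.0 ** (-ddct)
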