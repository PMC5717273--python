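"""Exact-test and FDR primitives used by the DMR caller.

Both are small enough to own outright, which keeps their tie-handling
and step-up conventions explicit and testable against independent
references (exact integer enumeration for the Fisher test, a naive
suffix-minimum loop and statsmodels for BH).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .model import MethylomeError

#: Relative slack when deciding whether an outcome's probability is
#: "no larger than" the observed table's: absorbs float rounding in the
#: hypergeometric pmf so exact ties land on the inclusive side.
_TIE_SLACK = 1e-12


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@lru_cache(maxsize=100_000)
def _hypergeom_pmf(n1: int, n2: int, k: int) -> np.ndarray:
    """pmf of a (row margins n1, n2; column margin k) 2x2 table family."""
    lo = max(0, k - n2)
    hi = min(n1, k)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_comb(n1, support) + _log_comb(n2, k - support)
        - _log_comb(n1 + n2, k)
    )
    return np.exp(logp)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums, conditional on all margins, the probabilities of every table
    whose hypergeometric probability does not exceed the observed one
    (with a tiny relative slack so exact ties are included). Returns a
    p in (0, 1].
    """
    if min(a, b, c, d) < 0:
        raise MethylomeError("negative count in contingency table")
    if a + b + c + d == 0:
        raise MethylomeError("empty contingency table")
    n1, n2, k = a + b, c + d, a + c
    pmf = _hypergeom_pmf(n1, n2, k)
    lo = max(0, k - n2)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_SLACK)].sum())
    return min(p, 1.0)


def fisher_exact_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vector form of :func:`fisher_exact_two_sided` (element-wise)."""
    out = np.empty(len(a), dtype=float)
    for i in range(len(a)):
        out[i] = fisher_exact_two_sided(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted
    p-values, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise MethylomeError("p-values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise MethylomeError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    scaled = p[order] * m / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def five_number_summary(values) -> dict[str, float]:
    """min / Q1 / median / Q3 / max with linear quartile interpolation."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise MethylomeError("empty value set")
    qs = np.percentile(x, [0, 25, 50, 75, 100])
    return {"min": qs[0], "q1": qs[1], "median": qs[2], "q3": qs[3], "max": qs[4]}
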