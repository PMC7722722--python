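"""One-sample Wilcoxon signed-rank test with an exact small-n null.

The cohort design pairs seven patients, so interaction calls hinge on exact
signed-rank p-values at n = 7 (the attainable p-values are multiples of
1/128).  The exact null is computed by dynamic programming over all 2^n sign
assignments of the (mid)ranks, which is identical to full enumeration and
also correct under ties.  Above ``exact_max_n`` observations a normal
approximation with tie correction and continuity correction is used.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata

__all__ = ["wilcoxon_greater_than_zero"]


def _exact_sf(double_ranks: np.ndarray, double_w: int) -> float:
    """P(W+ >= w) when each rank enters W+ with probability 1/2.

    Ranks are passed doubled so that midranks are integers.  The
    distribution of the doubled statistic is built by convolution; memory is
    O(sum of ranks), trivial for n <= 25.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(double_ranks)
    return float(counts[double_w:].sum() / 2.0**n)


def wilcoxon_greater_than_zero(
    scores, alpha: float = 0.05, exact_max_n: int = 25
) -> tuple[float, bool]:
    """One-sided (greater) one-sample Wilcoxon signed-rank test against zero.

    Zeros are dropped before ranking (the classic signed-rank convention);
    if every observation is zero the test is vacuous and ``p = 1``.

    Returns ``(p_value, significant)`` with ``significant = p < alpha``.
    """
    x = np.asarray(scores, dtype=np.float64)
    if x.size == 0:
        raise ValueError("no scores supplied")
    x = x[x != 0]
    n = x.size
    if n == 0:
        return 1.0, False
    ranks = rankdata(np.abs(x))
    w = ranks[x > 0].sum()
    if n <= exact_max_n:
        double_ranks = np.round(2 * ranks).astype(np.int64)
        double_w = int(np.round(2 * w))
        p = _exact_sf(double_ranks, double_w)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w - mean - 0.5) / np.sqrt(var)
        p = float(_norm.sf(z))
    p = min(p, 1.0)
    return p, p < alpha
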