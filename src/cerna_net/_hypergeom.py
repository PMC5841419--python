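"""Log-space cumulative (upper-tail) hypergeometric probabilities.

Shared numerical core of the shared-miRNA pair test and the gene-set
overrepresentation test.  Both ask the same question: given ``total``
balls of which ``n_a`` are marked, and a draw of ``n_b`` balls, how
probable is it to see at least ``overlap`` marked balls?

The sum is accumulated in log space (gammaln + logsumexp) so that
p-values far below float underflow of the individual terms remain
accurate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_upper_tail(overlap: int, total: int, n_a: int, n_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(total, n_a, n_b).

    Parameters
    ----------
    overlap : observed intersection size (lower limit of the sum).
    total : size of the common universe.
    n_a, n_b : sizes of the two sets drawn from the universe.

    Returns 1.0 when ``overlap <= max(0, n_a + n_b - total)`` (the sum
    covers the whole support) and 0.0 when ``overlap > min(n_a, n_b)``.
    """
    if total < 0 or n_a < 0 or n_b < 0:
        raise ValueError("total, n_a and n_b must be non-negative")
    if n_a > total or n_b > total:
        raise ValueError(
            f"set sizes ({n_a}, {n_b}) cannot exceed the universe size {total}"
        )
    hi = min(n_a, n_b)
    lo = max(0, n_a + n_b - total)
    if overlap <= lo:
        return 1.0
    if overlap > hi:
        return 0.0
    i = np.arange(overlap, hi + 1, dtype=float)
    log_terms = (
        _log_binom(float(n_a), i)
        + _log_binom(float(total - n_a), n_b - i)
        - _log_binom(float(total), float(n_b))
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)
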