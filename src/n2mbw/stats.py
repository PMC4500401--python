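"""Paired statistics used by the sensitivity harness.

The Wilcoxon signed-rank test follows the classic procedure: zero
differences are discarded, tied |differences| receive mid-ranks, the
two-sided p-value is exact (enumeration of all sign assignments) for
n <= 15 and a tie-corrected normal approximation above.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

EXACT_N_MAX = 15


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Returns ``(w_plus, p_two_sided)`` where ``w_plus`` is the sum of ranks
    of positive differences ``y - x``.  All-zero differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = y - x
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= EXACT_N_MAX:
        p = _exact_p(ranks, w_plus)
    else:
        p = _normal_p(ranks, w_plus, m)
    return w_plus, float(min(1.0, p))


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact conditional two-sided p by enumerating 2^m sign assignments."""
    m = len(ranks)
    # distribution of W+ over all sign vectors, built by convolution over
    # the (possibly tied, hence fractional) rank multiset
    scale = 2  # mid-ranks are multiples of 1/2
    weights = np.round(ranks * scale).astype(int)
    total = weights.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for w in weights:
        shifted = np.zeros_like(counts)
        shifted[w:] = counts[:counts.size - w]
        counts = counts + shifted
    counts /= 2.0 ** m
    w_scaled = int(round(w_plus * scale))
    p_le = counts[: w_scaled + 1].sum()
    p_ge = counts[w_scaled:].sum()
    return 2.0 * min(p_le, p_ge)


def _normal_p(ranks: np.ndarray, w_plus: float, m: int) -> float:
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    var -= ((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return 2.0 * norm.sf(abs(z))


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman agreement: (mean difference, lower LoA, upper LoA).

    Differences are ``y - x``; limits of agreement are the mean difference
    -/+ 1.96 sample standard deviations (ddof=1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd
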