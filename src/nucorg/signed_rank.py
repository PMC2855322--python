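"""Exact one-sided Wilcoxon signed-rank p-values for small samples.

The per-locus binding call rests on this primitive: with eleven probe
log2(IP/input) ratios per locus, the exact null distribution of the
positive-rank sum W+ is obtained by enumerating all 2^m sign assignments
of the m nonzero values (zeros are dropped; tied absolute values share
mid-ranks).  The enumeration is carried out as a convolution over the
per-value rank contributions, which is exactly the sum over sign
patterns.  For m above EXACT_LIMIT a normal approximation with tie
correction is used instead; the tiling designs handled here never exceed
eleven probes, so the exact path is the one exercised.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["signed_rank_pvalues", "EXACT_LIMIT"]

EXACT_LIMIT = 25


@lru_cache(maxsize=512)
def _null_counts(ranks2: tuple[int, ...]) -> np.ndarray:
    """Counts of sign assignments by doubled positive-rank sum.

    ``ranks2`` are the mid-ranks doubled to integers.  Entry w of the
    returned array is the number of the 2^m assignments whose doubled W+
    equals w; the array sums to 2^m.
    """
    total = int(sum(ranks2))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def signed_rank_pvalues(values) -> tuple[float, float]:
    """Return (p_up, p_down) for a one-sample signed-rank test against 0.

    p_up is P(W+ >= observed) under the null of sign-symmetry (evidence
    the values are shifted above zero); p_down is P(W+ <= observed).
    All-zero input returns (1.0, 1.0).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    v = v[v != 0.0]
    m = v.size
    if m == 0:
        return 1.0, 1.0

    ranks = rankdata(np.abs(v))  # mid-ranks for ties
    ranks2 = np.rint(2.0 * ranks).astype(int)
    w2 = int(ranks2[v > 0].sum())

    if m <= EXACT_LIMIT:
        counts = _null_counts(tuple(sorted(ranks2)))
        denom = float(2**m)
        p_up = float(counts[w2:].sum() / denom)
        p_down = float(counts[: w2 + 1].sum() / denom)
        return p_up, p_down

    # Normal approximation with tie correction on the doubled scale.
    mu = ranks2.sum() / 2.0
    sigma = np.sqrt((ranks2.astype(float) ** 2).sum() / 4.0)
    p_up = float(norm.sf((w2 - mu - 1.0) / sigma))
    p_down = float(norm.cdf((w2 - mu + 1.0) / sigma))
    return p_up, p_down
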