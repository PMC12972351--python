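"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: the
binomial tail is an exact big-integer / Fraction sum, the uniqueness
criterion a direct loop-over-rows reimplementation, and the PCA check a
full eigendecomposition of the covariance matrix.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def exact_binom_log10_sf(k: int, n: int, p0: Fraction = Fraction(1, 2)) -> float:
    """log10 P(X >= k) for X ~ Bin(n, p0) by exact rational summation."""
    p0 = Fraction(p0)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    if total == 0:
        raise ValueError("empty tail")
    # math.log10 handles arbitrarily large Python ints exactly enough
    return math.log10(total.numerator) - math.log10(total.denominator)


def brute_force_unique(values, tissues, margin=0.1, quantile=0.05, center="mean"):
    """Loop reimplementation of the uniqueness criterion.

    ``values``: 2D array (sites x samples) without missing handling;
    ``tissues``: per-column tissue labels.  Returns {(site_idx, tissue,
    direction)}.
    """
    values = np.asarray(values, float)
    labels = np.asarray(tissues)
    out = set()
    for t in np.unique(labels):
        t_cols = labels == t
        for i in range(values.shape[0]):
            tv = values[i, t_cols]
            ov = values[i, ~t_cols]
            c = np.mean(tv) if center == "mean" else np.median(tv)
            q_low = np.quantile(ov, quantile)
            q_high = np.quantile(ov, 1 - quantile)
            if c <= q_low - margin:
                out.add((i, str(t), "low"))
            elif c >= q_high + margin:
                out.add((i, str(t), "high"))
    return out


def pca_reconstruction_error(x: np.ndarray, n_components: int) -> float:
    """Best-rank-k reconstruction error via a full eigendecomposition
    of the sample covariance (independent of sklearn's SVD path)."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    basis = v[:, order[:n_components]]
    recon = xc @ basis @ basis.T
    return float(np.linalg.norm(xc - recon))
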