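"""Median-of-ratios size-factor normalization.

The published median-of-ratios procedure: each sample's size factor is the
median, over reference genes, of the ratio between the sample's count and
the across-sample geometric mean of that gene.  Reference genes are those
with strictly positive counts in every sample (a gene with any zero has no
finite geometric-mean log and is excluded).  Counts may be real-valued so
that convex count mixtures normalize the same way as raw integer counts.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix


def size_factors(m: CountMatrix) -> np.ndarray:
    """Per-sample median-of-ratios size factors.

    Raises
    ------
    ValueError
        If fewer than two samples are given or no gene is strictly
        positive in every sample (the geometric-mean reference is then
        undefined).
    """
    if m.n_samples < 2:
        raise ValueError("size factors need at least 2 samples")
    counts = m.counts
    reference = np.all(counts > 0, axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios size factors are undefined"
        )
    logc = np.log(counts[reference])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    return factors


def normalize_counts(m: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """Depth-normalized log expression: ``log2(count / factor + 1)``.

    Shape is preserved (genes x samples).  This is the classifier-facing
    transform; it is scale-invariant in the sense that doubling a sample's
    counts together with its size factor leaves the column unchanged.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.n_samples,):
        raise ValueError(
            f"expected {m.n_samples} size factors, got shape {factors.shape}"
        )
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        raise ValueError("size factors must be finite and > 0")
    return np.log2(m.counts / factors[None, :] + 1.0)
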