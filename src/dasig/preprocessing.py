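"""Expression preprocessing: quantile normalization and per-sample [0,1] scaling.

The autoencoder's input contract is a matrix whose every sample (column) lies
in [0,1]; the canonical route there is quantile normalization across samples
followed by per-sample min-max scaling x~ = (x - min x) / (max x - min x).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so all columns share one distribution.

    The reference distribution is the across-sample mean of sorted columns.
    Each value is replaced by the reference value at its within-column rank;
    ties receive the mean of the reference values at the tied ranks (mid-rank
    interpolation, the limma ``normalizeQuantiles`` dialect).

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 samples or 2 genes.
    """
    if X.n_samples < 2 or X.n_genes < 2:
        raise ValueError("quantile normalization needs >= 2 genes and >= 2 samples")
    V = X.values
    reference = np.sort(V, axis=0).mean(axis=1)  # length n_genes
    out = np.empty_like(V)
    positions = np.arange(1, X.n_genes + 1, dtype=float)
    for j in range(X.n_samples):
        ranks = rankdata(V[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent reference values
        out[:, j] = np.interp(ranks, positions, reference)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


def minmax_scale_samples(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample (column) to [0,1] by the min-max method.

    Raises
    ------
    ValueError
        If any sample is constant (max == min), naming the sample ID.
    """
    V = X.values
    lo = V.min(axis=0)
    hi = V.max(axis=0)
    constant = np.nonzero(hi <= lo)[0]
    if constant.size:
        bad = [X.sample_ids[j] for j in constant[:5]]
        raise ValueError(f"constant sample column(s), cannot min-max scale: {bad}")
    out = (V - lo) / (hi - lo)
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


def preprocess(X: ExpressionMatrix, skip_quantile: bool = False) -> ExpressionMatrix:
    """Standard preprocessing: quantile normalize (optional) then scale to [0,1]."""
    if not skip_quantile:
        X = quantile_normalize(X)
    return minmax_scale_samples(X)
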