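"""Count filtering, normalization and variable-gene selection.

Mirrors the standard UMI-style workflow: drop genes not expressed above a
count floor in enough samples, rescale each sample to the median total count,
keep the most over-dispersed genes relative to peers of similar mean
expression, and (optionally) summarize each matched pair by a log2 fold
change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import PairedExpression, RawCountMatrix

__all__ = [
    "filter_low_expression",
    "normalize_counts",
    "select_variable_genes",
    "log2_fold_change",
]


def filter_low_expression(
    raw: RawCountMatrix, min_count: int = 2, min_cells: int = 4
) -> RawCountMatrix:
    """Keep genes with count strictly greater than ``min_count`` in at least
    ``min_cells`` samples.  Gene order and the sample set are preserved.
    """
    if min_count < 0:
        raise ValueError("min_count must be nonnegative")
    if min_cells < 1:
        raise ValueError("min_cells must be at least 1")
    keep = (raw.counts > min_count).sum(axis=1) >= min_cells
    if not keep.any():
        warnings.warn("no genes pass the expression filter", UserWarning, stacklevel=2)
    return RawCountMatrix(counts=raw.counts.loc[keep], samples=raw.samples)


def normalize_counts(raw: RawCountMatrix) -> pd.DataFrame:
    """Scale each sample to the median total count.

    entry(g, s) = counts(g, s) / total(s) * median_s total(s); afterwards
    every sample sums to the median total.
    """
    totals = raw.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    return raw.counts / totals * float(totals.median())


def select_variable_genes(
    norm: pd.DataFrame, n_top: int = 2000, n_bins: int = 20
) -> list[str]:
    """Rank genes by dispersion (variance/mean) standardized within bins of
    similar mean expression; return the ``n_top`` most variable, descending.

    Genes are placed into ``n_bins`` equal-occupancy bins by mean expression;
    within each bin the dispersion is centered by the bin median and scaled
    by the bin median absolute deviation, so a gene is called variable only
    relative to genes of comparable abundance.
    """
    if n_top < 1:
        raise ValueError("n_top must be at least 1")
    p = norm.shape[0]
    if n_top > p:
        warnings.warn(
            f"n_top={n_top} exceeds the {p} available genes; returning all",
            UserWarning,
            stacklevel=2,
        )
        n_top = p

    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    disp = pd.Series(
        np.where(mean > 0, var / mean.replace(0, np.nan), 0.0), index=norm.index
    ).fillna(0.0)

    n_bins_eff = min(n_bins, max(1, p))
    # rank-based qcut gives equal-occupancy bins even with tied means
    bins = pd.qcut(mean.rank(method="first"), q=n_bins_eff, labels=False, duplicates="drop")

    z = pd.Series(0.0, index=norm.index)
    for b in np.unique(bins):
        idx = bins == b
        d = disp[idx]
        med = d.median()
        mad = (d - med).abs().median()
        if mad == 0:
            mad = (d - med).abs().mean()
        if mad == 0:
            z[idx] = 0.0
        else:
            z[idx] = (d - med) / mad

    order = sorted(range(p), key=lambda i: (-z.iloc[i], i))
    return [norm.index[i] for i in order[:n_top]]


def log2_fold_change(paired: PairedExpression, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-pair transcriptional response
    ``log2((tumor + pseudocount) / (normal + pseudocount))``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0:
        if (paired.normal <= 0).any().any() or (paired.tumor <= 0).any().any():
            raise ValueError("pseudocount 0 requires strictly positive expression")
    return np.log2((paired.tumor + pseudocount) / (paired.normal + pseudocount))
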