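"""Pseudo-counted quantile normalization, log transform, and feature selection.

Quantile normalization equalizes the per-sample intensity distributions:
after adding a pseudocount, each sample's sorted intensity vector is
replaced by the across-sample mean of order statistics, assigned back in
the sample's original rank order (ties receive the mean of their reference
quantiles).  The pseudocount keeps zero intensities strictly positive so a
log2 transform is always defined downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MetaboliteMatrix


def pq_normalize(matrix: MetaboliteMatrix, pseudocount: float = 1.0) -> MetaboliteMatrix:
    """Pseudo-counted quantile normalization across samples.

    Every sample (row) ends up with an identical sorted value multiset: the
    mean of the per-rank order statistics over all samples.  Tied values
    within a sample receive the mean of the reference quantiles their ranks
    span, so equal inputs map to equal outputs.
    """
    matrix.require_state("raw")
    x = matrix.to_numpy() + pseudocount
    if (x < 0).any():
        raise ValueError("raw intensities must be non-negative before pseudocount")
    order = np.argsort(x, axis=1, kind="stable")
    reference = np.sort(x, axis=1).mean(axis=0)  # mean of order statistics
    out = np.empty_like(x)
    n_samp, n_met = x.shape
    rows = np.arange(n_samp)[:, None]
    out[rows, order] = reference[None, :].repeat(n_samp, axis=0)
    # tie handling: within each row, equal input values get the mean of the
    # reference quantiles assigned across their ranks
    for i in range(n_samp):
        vals = x[i]
        uniq, inv, counts = np.unique(vals, return_inverse=True, return_counts=True)
        if len(uniq) < n_met:
            sums = np.bincount(inv, weights=out[i])
            out[i] = (sums / counts)[inv]
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df, "normalized")


def log2_median_center(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """log2-transform then subtract the per-metabolite median.

    Requires a normalized matrix with strictly positive entries; output
    columns have median exactly zero.
    """
    matrix.require_state("normalized")
    x = matrix.to_numpy()
    if (x <= 0).any():
        i, j = np.argwhere(x <= 0)[0]
        raise ValueError(
            f"non-positive entry at sample {matrix.sample_ids[i]!r}, "
            f"metabolite {matrix.metabolite_names[j]!r}: {x[i, j]}"
        )
    logged = np.log2(x)
    centered = logged - np.median(logged, axis=0, keepdims=True)
    df = pd.DataFrame(centered, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(df, "log2_centered")


def top_variable(matrix: MetaboliteMatrix, n: int = 100) -> MetaboliteMatrix:
    """Keep the n metabolites of largest (unbiased) sample variance.

    Retained metabolites are ordered by descending variance; exact variance
    ties are broken by metabolite name order so the selection is
    deterministic.
    """
    matrix.require_state("log2_centered")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > matrix.n_metabolites:
        raise ValueError(f"n={n} exceeds metabolite count {matrix.n_metabolites}")
    var = matrix.values.var(axis=0, ddof=1)
    # stable sort on (-variance, name): pre-sort by name so ties fall in name order
    by_name = var.loc[sorted(var.index)]
    ranked = by_name.sort_values(ascending=False, kind="stable")
    keep = list(ranked.index[:n])
    return matrix.with_values(matrix.values[keep], "log2_centered")
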