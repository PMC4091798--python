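"""Count aggregation, expression calling, and count normalization factors.

RNA-seq expression is quantified at the transcript-variant level and summed
to genes. A gene counts as expressed in a sample when it has at least 5
mapped reads (raw counts, before any normalization). Two normalization
schemes are provided: TMM (trimmed mean of M-values, the edgeR scheme) for
the differential-expression path, and DESeq-style median-of-ratios size
factors for the heatmap/display path.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .homology import variant_gene


def gene_counts(variant_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum variant-level counts to genes; per-sample totals are conserved."""
    genes = [variant_gene(v, warn=False) for v in variant_counts.index]
    out = variant_counts.groupby(pd.Index(genes, name="gene")).sum()
    return out.sort_index()


def expressed_genes(counts: pd.DataFrame, min_reads: int = 5) -> dict[str, set[str]]:
    """Per-sample sets of genes with at least ``min_reads`` raw counts."""
    return {sample: set(counts.index[counts[sample] >= min_reads])
            for sample in counts.columns}


def _tmm_pair_log2(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
                   logratio_trim: float, abs_trim: float) -> float:
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask].astype(float), ref[mask].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic (delta-method) variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return 0.0 if abs(f) < 1e-10 else f


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05, ref_column: str | None = None) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    Per sample versus the reference column, the factor is 2 to the weighted
    mean of doubly trimmed (30% on M, 5% on A) per-gene log-ratios of
    library-size-scaled counts, weighted by inverse asymptotic variances.
    Genes with a zero in either member of a pair are excluded from that
    pair's trimmed mean. The reference is the column whose upper quartile of
    scaled counts is closest to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError(f"samples with all-zero counts: "
                         f"{list(lib.index[lib == 0])}")
    values = counts.to_numpy(dtype=float)
    if ref_column is None:
        uq = np.array([np.quantile(values[:, j], 0.75) / lib.iloc[j]
                       for j in range(values.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_column)
    ref = values[:, ref_idx]
    n_ref = lib.iloc[ref_idx]
    log_f = np.array([
        _tmm_pair_log2(values[:, j], ref, lib.iloc[j], n_ref, logratio_trim, abs_trim)
        for j in range(values.shape[1])
    ])
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios size factors.

    factor_j = median over all-nonzero genes of count_gj / geomean_g(count).
    """
    values = counts.to_numpy(dtype=float)
    nonzero = (values > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = values[nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="median_ratio")


def factors_frame(factors: pd.Series, method: str) -> pd.DataFrame:
    """Serializable factor table: ``sample, factor, method``."""
    return pd.DataFrame({"sample": factors.index, "factor": factors.values,
                         "method": method})
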