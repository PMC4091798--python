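"""Heatmap-path numerics: normalized log2 display values and hierarchical clustering.

Only the numbers behind a heatmap are produced (merge tree, leaf order,
scaled matrix); rendering is out of scope.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist


def row_scale_log2(counts: pd.DataFrame, size_factors: pd.Series,
                   pseudocount: float = 1.0, center: bool = False,
                   scale: bool = False) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), optionally row-centred/scaled.

    Size factors must be positive; doubling a column's counts and its factor
    leaves the output unchanged.
    """
    factors = size_factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    values = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy() + pseudocount)
    if center or scale:
        values = values - values.mean(axis=1, keepdims=True)
    if scale:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        values = np.divide(values, sd, out=np.zeros_like(values), where=sd > 0)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def hcluster(matrix: pd.DataFrame, metric: str = "euclidean",
             method: str = "complete") -> tuple[np.ndarray, list]:
    """Agglomerative clustering of rows; returns (linkage matrix, leaf ids).

    Rows are pre-sorted by id so equal-distance merges break ties
    deterministically.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix must be finite")
    ordered = matrix.sort_index(kind="stable")
    z = linkage(pdist(ordered.to_numpy(dtype=float), metric=metric), method=method)
    leaf_order = [ordered.index[i] for i in leaves_list(z)]
    return z, leaf_order
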