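"""Probe-level summarization and negative-probeset presence/absence calls.

The array path is a deliberately light RMA variant: log2 transform, quantile
normalization across arrays, then per-probeset two-way median polish (no
normal-exponential background correction). Presence p-values come from the
empirical survivor function of the *negative* probesets' summarized
expression — probesets whose probes do not align to the sample species'
transcriptome and therefore measure pure background. A probeset far above
every negative value gets p = 0; one at or below the negative minimum gets
p = 1; in between, the survivor function is linearly interpolated between the
unique sorted negative values, with ties sharing the conservative (larger)
value. Calls: P if p <= p_present (default 0.02), M up to p_marginal, else A.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the per-rank cross-column mean distribution.

    Within-column rank order is preserved; tied values within a column receive
    the mean of the values their ranks would have been assigned.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = mean_sorted
        # average over ties so equal inputs map to equal outputs
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 0.01):
    """Tukey two-way median polish.

    Returns ``(overall, row_effects, col_effects, residuals)`` with
    ``matrix ≈ overall + row + col + residuals``. Sweeps alternate row and
    column medians; iteration stops when the total absolute residual changes
    by less than ``tol`` between sweeps, or after ``max_iter`` sweeps.
    """
    z = np.asarray(matrix, dtype=float).copy()
    if z.ndim != 2:
        raise ValueError("median polish expects a 2-D matrix")
    nrow, ncol = z.shape
    overall = 0.0
    row = np.zeros(nrow)
    col = np.zeros(ncol)
    oldsum = np.abs(z).sum()
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        newsum = np.abs(z).sum()
        if abs(newsum - oldsum) < tol:
            break
        oldsum = newsum
    return overall, row, col, z


def summarize_probesets(log_matrix: pd.DataFrame, library: pd.DataFrame,
                        max_iter: int = 10, tol: float = 0.01) -> pd.DataFrame:
    """Summarize a probes x arrays log2 matrix to probeset expression.

    Per probeset, the array-wise expression is the median-polish overall
    effect plus the array (column) effect. A single-probe probeset passes
    through unchanged.
    """
    probe_to_set = dict(zip(library["probe_id"], library["probeset_id"]))
    unknown = [p for p in log_matrix.index if p not in probe_to_set]
    if unknown:
        raise ValueError(f"probes missing from the library: {unknown[:5]}")
    groups: dict[str, list[str]] = {}
    for probe in log_matrix.index:
        groups.setdefault(probe_to_set[probe], []).append(probe)
    rows = {}
    for probeset in sorted(groups):
        block = log_matrix.loc[groups[probeset]].to_numpy(dtype=float)
        if block.shape[0] == 1:
            rows[probeset] = block[0]
        else:
            overall, _, col, _ = median_polish(block, max_iter=max_iter, tol=tol)
            rows[probeset] = overall + col
    return pd.DataFrame.from_dict(rows, orient="index", columns=log_matrix.columns)


def rma_lite(intensities: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """log2 -> quantile normalization -> median-polish summarization."""
    values = intensities.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("intensities must be strictly positive for log2 transform")
    logged = pd.DataFrame(np.log2(values), index=intensities.index,
                          columns=intensities.columns)
    return summarize_probesets(quantile_normalize(logged), library)


def _survivor_pvalues(values: np.ndarray, negatives: np.ndarray) -> np.ndarray:
    neg_sorted = np.sort(negatives)
    unique = np.unique(neg_sorted)
    m = len(neg_sorted)
    # survivor S(u) = #(negatives >= u) / m at each unique negative value
    survivor = (m - np.searchsorted(neg_sorted, unique, side="left")) / m
    p = np.interp(values, unique, survivor)
    p = np.where(values > unique[-1], 0.0, p)
    p = np.where(values <= unique[0], 1.0, p)
    return p


def panp_pvalues(expression: pd.DataFrame, negatives: Iterable[str],
                 min_negatives: int = 50) -> pd.DataFrame:
    """Per-array presence p-values from the negative-probeset distribution."""
    negative_ids = sorted(set(negatives) & set(expression.index))
    if len(negative_ids) < min_negatives:
        raise ValueError(
            f"only {len(negative_ids)} negative probesets available "
            f"(minimum {min_negatives}) for arrays {list(expression.columns)}")
    out = {}
    for array in expression.columns:
        neg = expression.loc[negative_ids, array].to_numpy(dtype=float)
        out[array] = _survivor_pvalues(expression[array].to_numpy(dtype=float), neg)
    return pd.DataFrame(out, index=expression.index)


def pa_calls(pvalues: pd.DataFrame, p_present: float = 0.02,
             p_marginal: float = 0.04) -> pd.DataFrame:
    """Present / Marginal / Absent calls from presence p-values."""
    if not 0 < p_present <= p_marginal <= 1:
        raise ValueError("thresholds must satisfy 0 < p_present <= p_marginal <= 1")
    values = pvalues.to_numpy(dtype=float)
    calls = np.where(values <= p_present, "P", np.where(values <= p_marginal, "M", "A"))
    return pd.DataFrame(calls, index=pvalues.index, columns=pvalues.columns)


def calls_long(pvalues: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Long-format call table: ``probeset, array, p, call``."""
    rows = []
    for array in pvalues.columns:
        for probeset in pvalues.index:
            rows.append((probeset, array, pvalues.at[probeset, array],
                         calls.at[probeset, array]))
    return pd.DataFrame(rows, columns=["probeset", "array", "p", "call"])
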