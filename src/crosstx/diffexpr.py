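"""Replicate-free differential expression for single-sample count libraries.

Two complementary routes, both designed for experiments without biological
replicates:

* NOISeq-sim: technical replicates are simulated by multinomial subsampling
  of each library (``nss`` replicates at a fraction ``pnr`` of the library,
  jittered by ``v``). All within-sample replicate pairs define a noise cloud
  of (|M|, D) points — M the log2 ratio, D the absolute difference of
  normalized values. A gene's DE probability is the fraction of noise points
  it dominates (non-strict, in both coordinates); genes with prob > q
  (default 0.9) are declared differentially expressed.

* Exact negative-binomial test at fixed dispersion: with no replicates the
  dispersion cannot be estimated, so it is fixed from an assumed biological
  coefficient of variation (bcv 0.8, dispersion = bcv^2 = 0.64). Libraries
  are equalized to their geometric-mean size via rounded pseudo-counts;
  conditional on the pseudo-count total, the two-sided p-value sums the
  probabilities of all splits no more likely than the observed one.

Benjamini-Hochberg adjustment and the focal-cell enrichment set rules
(up-in-focal in *all* pairwise comparisons) complete the module.
"""
from __future__ import annotations

import bisect
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests


def _normalize_column(raw: np.ndarray, effective_size: float, scale: float,
                      k: float) -> np.ndarray:
    values = raw.astype(float).copy()
    values[values == 0] = k
    return values / effective_size * scale


def noiseq_sim(counts: pd.DataFrame, sample_a: str, sample_b: str,
               norm_factors: pd.Series | None = None, pnr: float = 0.2,
               nss: int = 5, v: float = 0.02, k: float = 0.5,
               seed: int = 42) -> tuple[pd.DataFrame, np.ndarray]:
    """NOISeq-sim DE probabilities for one pairwise contrast.

    Returns ``(results, noise)`` where ``results`` has columns
    ``gene, M, D, prob`` (M > 0 means higher in ``sample_a``) and ``noise``
    is the pooled (|M|, D) array from simulated within-sample replicate
    pairs. Deterministic under ``seed``.
    """
    if pnr - v <= 0:
        raise ValueError("pnr - v must be positive")
    for sample in (sample_a, sample_b):
        if sample not in counts.columns:
            raise ValueError(f"sample {sample!r} not in count table")
        if counts[sample].sum() == 0:
            raise ValueError(f"sample {sample!r} is empty")
    rng = np.random.default_rng(seed)
    raw_a = counts[sample_a].to_numpy()
    raw_b = counts[sample_b].to_numpy()
    fac_a = float(norm_factors[sample_a]) if norm_factors is not None else 1.0
    fac_b = float(norm_factors[sample_b]) if norm_factors is not None else 1.0
    eff_a = raw_a.sum() * fac_a
    eff_b = raw_b.sum() * fac_b
    scale = 0.5 * (eff_a + eff_b)

    za = _normalize_column(raw_a, eff_a, scale, k)
    zb = _normalize_column(raw_b, eff_b, scale, k)
    m_signal = np.log2(za / zb)
    d_signal = np.abs(za - zb)

    noise_m, noise_d = [], []
    for raw, factor in ((raw_a, fac_a), (raw_b, fac_b)):
        total = int(raw.sum())
        props = raw / total
        replicates = []
        for _ in range(nss):
            size = int(round(rng.uniform(pnr - v, pnr + v) * total))
            rep = rng.multinomial(size, props)
            replicates.append(_normalize_column(rep, size * factor, scale, k))
        for r1, r2 in combinations(replicates, 2):
            noise_m.append(np.abs(np.log2(r1 / r2)))
            noise_d.append(np.abs(r1 - r2))
    abs_m_noise = np.concatenate(noise_m)
    d_noise = np.concatenate(noise_d)

    prob = dominated_fraction(np.abs(m_signal), d_signal, abs_m_noise, d_noise)
    results = pd.DataFrame({"gene": counts.index, "M": m_signal, "D": d_signal,
                            "prob": prob}).set_index("gene")
    return results, np.column_stack([abs_m_noise, d_noise])


def dominated_fraction(abs_m: np.ndarray, d: np.ndarray, abs_m_noise: np.ndarray,
                       d_noise: np.ndarray) -> np.ndarray:
    """Fraction of noise points dominated (non-strictly) in both coordinates.

    Sort-based: noise is ordered by |M|; for each signal point, the candidate
    noise points with |M*| <= |M| are a prefix, within which D* <= D is
    counted via a running sorted structure.
    """
    order = np.argsort(abs_m_noise, kind="stable")
    m_sorted = abs_m_noise[order]
    d_by_m = d_noise[order]
    n = len(m_sorted)
    out = np.empty(len(abs_m))
    sig_order = np.argsort(abs_m, kind="stable")
    prefix = 0
    d_tree: list[float] = []
    for idx in sig_order:
        limit = np.searchsorted(m_sorted, abs_m[idx], side="right")
        while prefix < limit:
            bisect.insort(d_tree, d_by_m[prefix])
            prefix += 1
        out[idx] = bisect.bisect_right(d_tree, d[idx]) / n
    return out


def noiseq_enriched(results: Mapping[str, pd.DataFrame], q: float = 0.9) -> set[str]:
    """Genes enriched in the focal sample: prob > q and M > 0 in all 3 contrasts."""
    if len(results) != 3:
        raise ValueError(f"expected results for 3 contrasts, got {len(results)}")
    sets = []
    for contrast, df in results.items():
        sets.append(set(df.index[(df["prob"] > q) & (df["M"] > 0)]))
    return set.intersection(*sets)


def exact_nb_test(x1: int, x2: int, n1: float, n2: float,
                  dispersion: float = 0.64) -> float:
    """Two-sided exact test for one gene's counts in two libraries.

    Counts are converted to pseudo-counts at the geometric-mean library size
    (rounded); conditional on their total ``s``, each split follows the
    distribution of one of two i.i.d. NB(mean s/2, dispersion) variables given
    their sum. The p-value sums the probabilities of all splits whose
    probability does not exceed the observed one. ``dispersion = 0`` is the
    Poisson limit, where the conditional law is Binomial(s, 1/2).
    """
    if x1 < 0 or x2 < 0 or int(x1) != x1 or int(x2) != x2:
        raise ValueError("counts must be nonnegative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    n_star = np.sqrt(n1 * n2)
    y1 = int(np.rint(x1 * n_star / n1))
    y2 = int(np.rint(x2 * n_star / n2))
    s = y1 + y2
    if s == 0:
        return 1.0
    support = np.arange(s + 1)
    if dispersion == 0:
        pmf = binom.pmf(support, s, 0.5)
    else:
        r = 1.0 / dispersion
        mu = s / 2.0
        p_nb = r / (r + mu)
        marg = nbinom.pmf(support, r, p_nb)
        pmf = marg * marg[::-1]
        pmf = pmf / pmf.sum()
    p_obs = pmf[y1]
    mask = pmf <= p_obs * (1 + 1e-9)
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def exact_nb_contrast(counts: pd.DataFrame, sample_a: str, sample_b: str,
                      dispersion: float = 0.64,
                      norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene exact NB tests for one contrast with BH adjustment.

    Returns columns ``logFC, p_value, fdr``; logFC > 0 means higher in
    ``sample_a`` (computed with a half-count offset on library-scaled counts).
    """
    fac_a = float(norm_factors[sample_a]) if norm_factors is not None else 1.0
    fac_b = float(norm_factors[sample_b]) if norm_factors is not None else 1.0
    n1 = counts[sample_a].sum() * fac_a
    n2 = counts[sample_b].sum() * fac_b
    x1 = counts[sample_a].to_numpy()
    x2 = counts[sample_b].to_numpy()
    pvals = np.array([exact_nb_test(a, b, n1, n2, dispersion)
                      for a, b in zip(x1, x2)])
    logfc = np.log2(((x1 + 0.5) / n1) / ((x2 + 0.5) / n2))
    return pd.DataFrame({"logFC": logfc, "p_value": pvals,
                         "fdr": bh_adjust(pvals)}, index=counts.index)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exact_test_enriched(pairwise: Mapping[tuple[str, str], pd.DataFrame],
                        focal: str, fdr_cut: float = 0.05, raw_cut: float = 0.001,
                        special_pair: tuple[str, str] | None = None
                        ) -> tuple[set[str], set[str]]:
    """Focal-enriched genes and the union of pairwise-DE genes.

    ``pairwise`` maps (first, second) sample pairs to result frames from
    :func:`exact_nb_contrast` (logFC oriented first-over-second). A gene is
    focal-enriched when it is up in the focal sample with fdr < ``fdr_cut``
    in *every* pairwise comparison involving the focal sample; for the
    designated ``special_pair`` an unadjusted p < ``raw_cut`` substitutes for
    the fdr rule. The second returned set is the union of genes significant
    (either direction) in any comparison, under the same per-pair rule.
    """
    def significant(pair: tuple[str, str], df: pd.DataFrame) -> pd.Series:
        if "fdr" not in df.columns:
            raise ValueError(f"results for pair {pair} lack an fdr column")
        if special_pair is not None and frozenset(pair) == frozenset(special_pair):
            return df["p_value"] < raw_cut
        return df["fdr"] < fdr_cut

    focal_sets = []
    union: set[str] = set()
    for pair, df in pairwise.items():
        sig = significant(pair, df)
        union |= set(df.index[sig])
        if focal in pair:
            up = df["logFC"] > 0 if pair[0] == focal else df["logFC"] < 0
            focal_sets.append(set(df.index[sig & up]))
    if not focal_sets:
        raise ValueError(f"no pairwise comparison involves focal sample {focal!r}")
    return set.intersection(*focal_sets), union
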