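"""Independent reference implementations used only to check the package.

Each oracle is written as a direct transcription of the defining rule
(brute force, full enumeration, closed form), deliberately sharing no code
path with the implementation it validates.
"""
from __future__ import annotations

import math
import statistics
from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_probe_scan(probe: str, transcriptome: dict[str, str], max_mismatches: int
                     ) -> list[tuple[str, int, str, int]]:
    """Sliding-window Hamming scan over both strands, all offsets, all targets.

    Returns (target_id, start, strand, mismatches) tuples, sorted.
    """
    hits = []
    rc = "".join(_COMP[b] for b in reversed(probe))
    plen = len(probe)
    for strand, query in (("+", probe), ("-", rc)):
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        for tid, seq in transcriptome.items():
            tarr = np.frombuffer(seq.encode(), dtype=np.uint8)
            if len(tarr) < plen:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(tarr, plen)
            mism = (windows != qarr).sum(axis=1)
            for start in np.flatnonzero(mism <= max_mismatches):
                hits.append((tid, int(start), strand, int(mism[start])))
    return sorted(hits)


def quantile_normalize_by_definition(matrix: np.ndarray) -> np.ndarray:
    """Rank-by-rank mean assignment with explicit tie averaging."""
    nrow, ncol = matrix.shape
    target = np.mean(np.stack([sorted(matrix[:, j]) for j in range(ncol)]), axis=0)
    out = np.empty_like(matrix, dtype=float)
    for j in range(ncol):
        col = list(matrix[:, j])
        order = sorted(range(nrow), key=lambda i: col[i])
        assigned = [0.0] * nrow
        for rank, i in enumerate(order):
            assigned[i] = target[rank]
        for value in set(col):
            idx = [i for i in range(nrow) if col[i] == value]
            mean = sum(assigned[i] for i in idx) / len(idx)
            for i in idx:
                assigned[i] = mean
        out[:, j] = assigned
    return out


def median_polish_iterative(matrix, max_iter=10, tol=0.01):
    """Plain-loop Tukey median polish (row sweep, column sweep, recentring)."""
    z = [list(map(float, row)) for row in matrix]
    nrow, ncol = len(z), len(z[0])
    overall, row, col = 0.0, [0.0] * nrow, [0.0] * ncol
    oldsum = sum(abs(v) for r in z for v in r)
    for _ in range(max_iter):
        for i in range(nrow):
            med = statistics.median(z[i])
            row[i] += med
            for j in range(ncol):
                z[i][j] -= med
        med = statistics.median(col)
        overall += med
        for j in range(ncol):
            col[j] -= med
        for j in range(ncol):
            med = statistics.median(z[i][j] for i in range(nrow))
            col[j] += med
            for i in range(nrow):
                z[i][j] -= med
        med = statistics.median(row)
        overall += med
        for i in range(nrow):
            row[i] -= med
        newsum = sum(abs(v) for r in z for v in r)
        if abs(newsum - oldsum) < tol:
            break
        oldsum = newsum
    return overall, row, col, z


def survivor_pvalue(x: float, negatives: list[float]) -> float:
    """Interpolated empirical survivor function of the negatives at x."""
    uniq = sorted(set(negatives))
    m = len(negatives)
    surv = [sum(1 for v in negatives if v >= u) / m for u in uniq]
    if x <= uniq[0]:
        return 1.0
    if x > uniq[-1]:
        return 0.0
    for i in range(len(uniq) - 1):
        if uniq[i] <= x <= uniq[i + 1]:
            if x == uniq[i]:
                return surv[i]
            frac = (x - uniq[i]) / (uniq[i + 1] - uniq[i])
            return surv[i] + frac * (surv[i + 1] - surv[i])
    return surv[-1]


def tmm_oracle(counts, logratio_trim=0.3, abs_trim=0.05, ref_column=None):
    """Step-by-step TMM with explicit sorting-based trims (pandas-free)."""
    samples = list(counts.columns)
    x = {s: [float(v) for v in counts[s]] for s in samples}
    lib = {s: sum(x[s]) for s in samples}
    if ref_column is None:
        uq = {}
        for s in samples:
            vals = sorted(x[s])
            uq[s] = np.quantile(np.array(vals), 0.75) / lib[s]
        mean_uq = sum(uq.values()) / len(samples)
        ref = min(samples, key=lambda s: (abs(uq[s] - mean_uq), samples.index(s)))
    else:
        ref = ref_column
    logf = {}
    for s in samples:
        pairs = [(o, r) for o, r in zip(x[s], x[ref]) if o > 0 and r > 0]
        m, a, w = [], [], []
        for o, r in pairs:
            po, pr = o / lib[s], r / lib[ref]
            m.append(math.log2(po / pr))
            a.append(0.5 * math.log2(po * pr))
            w.append((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(m)
        if n == 0:
            logf[s] = 0.0
            continue
        def ranks(values):
            order = sorted(range(n), key=lambda i: values[i])
            rk = [0.0] * n
            i = 0
            while i < n:
                j = i
                while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for t in range(i, j + 1):
                    rk[order[t]] = avg
                i = j + 1
            return rk
        rm, ra = ranks(m), ranks(a)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        keep = [i for i in range(n)
                if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a]
        if not keep:
            logf[s] = 0.0
        else:
            num = sum(w[i] * m[i] for i in keep)
            den = sum(w[i] for i in keep)
            f = num / den if den else 0.0
            logf[s] = 0.0 if abs(f) < 1e-10 else f
    factors = {s: 2.0 ** logf[s] for s in samples}
    geo = math.exp(sum(math.log(f) for f in factors.values()) / len(samples))
    return {s: f / geo for s, f in factors.items()}


def median_ratio_oracle(counts):
    """Direct DESeq formula: median over all-nonzero genes of count/geomean."""
    samples = list(counts.columns)
    rows = [list(map(float, counts.loc[g])) for g in counts.index
            if all(counts.loc[g] > 0)]
    out = {}
    for j, s in enumerate(samples):
        ratios = []
        for row in rows:
            geo = math.exp(sum(math.log(v) for v in row) / len(row))
            ratios.append(row[j] / geo)
        out[s] = statistics.median(ratios)
    return out


def _log_nb_pmf(k: int, r: float, mu: float) -> float:
    p = r / (r + mu)
    return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(p) + k * math.log1p(-p))


def exact_nb_enumeration(y1: int, y2: int, dispersion: float) -> float:
    """Full-support enumeration of the conditional two-sided NB test."""
    s = y1 + y2
    if s == 0:
        return 1.0
    mu = s / 2.0
    if dispersion == 0:
        logs = [math.lgamma(s + 1) - math.lgamma(a + 1) - math.lgamma(s - a + 1)
                - s * math.log(2.0) for a in range(s + 1)]
    else:
        r = 1.0 / dispersion
        logs = [_log_nb_pmf(a, r, mu) + _log_nb_pmf(s - a, r, mu)
                for a in range(s + 1)]
    mx = max(logs)
    weights = [math.exp(v - mx) for v in logs]
    total = sum(weights)
    obs = weights[y1]
    p = sum(w for w in weights if w <= obs * (1 + 1e-9)) / total
    return min(p, 1.0)


def bh_closed_form(p_values):
    """q_i = min_{j >= i} p_(j) * m / j over the ascending order statistics."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p_values[i] * m / (rank + 1))
        adjusted[i] = running
    return adjusted


def _log_hypergeom_pmf(k, big_n, big_k, n):
    return (math.lgamma(big_k + 1) - math.lgamma(k + 1) - math.lgamma(big_k - k + 1)
            + math.lgamma(big_n - big_k + 1) - math.lgamma(n - k + 1)
            - math.lgamma(big_n - big_k - n + k + 1)
            - (math.lgamma(big_n + 1) - math.lgamma(n + 1)
               - math.lgamma(big_n - n + 1)))


def fisher_upper_tail(k, big_n, big_k, n):
    """One-sided overrepresentation p by pmf summation over the upper tail."""
    lo = max(0, n + big_k - big_n)
    hi = min(n, big_k)
    return min(sum(math.exp(_log_hypergeom_pmf(a, big_n, big_k, n))
                   for a in range(k, hi + 1)), 1.0)


def fisher_two_sided_enumeration(k, big_n, big_k, n):
    """Minimum-likelihood two-sided p by enumeration over the full support.

    The pmf is built by the mode-anchored ratio recurrence
    pmf(a+1)/pmf(a) = (K-a)(n-a) / ((a+1)(N-K-n+a+1)) and normalized with an
    exact compensated sum, keeping every term accurate to a few ulp.
    """
    lo = max(0, n + big_k - big_n)
    hi = min(n, big_k)
    mode = (n + 1) * (big_k + 1) // (big_n + 2)
    mode = min(max(mode, lo), hi)
    raw = {mode: 1.0}
    for a in range(mode, hi):
        ratio = (big_k - a) * (n - a) / ((a + 1) * (big_n - big_k - n + a + 1))
        raw[a + 1] = raw[a] * ratio
    for a in range(mode, lo, -1):
        ratio = a * (big_n - big_k - n + a) / ((big_k - a + 1) * (n - a + 1))
        raw[a - 1] = raw[a] * ratio
    total = math.fsum(raw.values())
    obs = raw[k]
    sel = math.fsum(w for w in raw.values() if w <= obs * (1 + 1e-11))
    return min(sel / total, 1.0)


def dominated_recount(abs_m, d, abs_m_noise, d_noise):
    """Quadratic recount of dominated noise points."""
    n = len(abs_m_noise)
    out = []
    for am, dd in zip(abs_m, d):
        out.append(sum(1 for mm, dn in zip(abs_m_noise, d_noise)
                       if mm <= am and dn <= dd) / n)
    return out


def complete_linkage_bruteforce(points):
    """Agglomerative complete-linkage merges on euclidean distances.

    Returns the list of merged index-sets in merge order (each as a frozenset
    of original row indices).
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    clusters = [frozenset([i]) for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best, pair = None, None
        for a, b in combinations(range(len(clusters)), 2):
            dist = max(np.linalg.norm(pts[i] - pts[j])
                       for i in clusters[a] for j in clusters[b])
            if best is None or dist < best - 1e-12:
                best, pair = dist, (a, b)
        a, b = pair
        merged = clusters[a] | clusters[b]
        merges.append((merged, best))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return merges
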