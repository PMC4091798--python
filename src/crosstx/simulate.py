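"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the data shapes of a cross-species germline
transcriptomics study: a de novo transcriptome with ``comp<x>_c<y>_seq<z>``
variant ids; 25-mer probesets that diverge from their targets by a per-base
substitution rate (the cross-species mismatch regime) plus a fraction of
off-target probesets (true background sensors); log-normal background/signal
intensity mixtures with per-probe affinity effects; negative-binomial counts
at fixed dispersion 0.64 (a biological coefficient of variation of 0.8, the
replicate-free assumption of the analysis) with cell-type-specific fold
changes; a rooted is_a ontology with direct-only annotations; and homologous
gene pairs emitted as valid 21-column PSL with decoy alignments.

One global seed drives everything; each generator derives its own stream
from (seed, stage index), so stages are independently reproducible and a
fixed configuration re-emits byte-identical files.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import PslRecord, variant_gene

_BASES = np.array(list("ACGT"))

# stage indices for deterministic per-generator sub-streams
STAGE_TRANSCRIPTOME = 0
STAGE_PROBES = 1
STAGE_INTENSITIES = 2
STAGE_TRUTH = 3
STAGE_COUNTS = 4
STAGE_ANNOTATIONS = 5
STAGE_PSL = 6


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Intensity parameters are on the log2 scale; the default signal sits three
    background standard deviations above the background mean. Dispersion is
    the negative-binomial dispersion (variance = mu + dispersion * mu^2);
    0.64 corresponds to a biological coefficient of variation of 0.8.
    """

    seed: int = 42
    # transcriptome
    n_genes: int = 300
    variants_per_gene: int | tuple[str, float] = 1
    length_mean: float = 1000.0
    length_sd: float = 200.0
    min_length: int = 200
    variant_divergence: float = 0.01
    # probes
    n_probesets: int = 120
    probes_per_set: int = 11
    probe_length: int = 25
    probe_divergence_rate: float = 0.02
    off_target_fraction: float = 0.3
    # array intensities (log2 scale)
    background_mean: float = 6.0
    background_sd: float = 1.0
    signal_mean: float = 9.0
    signal_sd: float = 1.0
    probe_effect_sd: float = 0.5
    # counts
    dispersion: float = 0.64
    baseline_mean: float = 100.0
    baseline_sigma: float = 1.0
    library_sizes: tuple[int, ...] | None = None
    de_fraction: float = 0.1
    fold_change: float = 4.0
    silent_fraction: float = 0.15
    samples: tuple[str, ...] = ("aic", "egg", "central", "synergid")

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be nonnegative")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if not 0 <= self.probe_divergence_rate <= 1:
            raise ConfigurationError("probe_divergence_rate must be in [0, 1]")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")
        if self.signal_mean <= self.background_mean:
            warnings.warn("signal mean does not exceed background mean; "
                          "presence-call power will be near the nominal FPR")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), stage])


@dataclass
class TruthTable:
    """Ground truth behind one simulated dataset."""

    genes: list[str]
    samples: list[str]
    expressed_in: dict[str, set[str]]          # gene -> sample labels
    fold_change: pd.DataFrame                  # genes x samples, > 0
    markers: dict[str, str] = field(default_factory=dict)  # gene -> focal sample
    homologue_of: dict[str, str | None] = field(default_factory=dict)
    terms: dict[str, set[str]] = field(default_factory=dict)
    families: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError("gene ids must be unique")
        if (self.fold_change.to_numpy() <= 0).any():
            raise ConfigurationError("fold changes must be positive")
        labels = set(self.samples)
        for gene, where in self.expressed_in.items():
            if not where <= labels:
                raise ConfigurationError(f"unknown sample labels for {gene}: "
                                         f"{sorted(where - labels)}")


def _variant_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.variants_per_gene
    if isinstance(spec, int):
        if spec < 1:
            raise ConfigurationError("variants_per_gene must be >= 1")
        return np.full(config.n_genes, spec)
    if isinstance(spec, tuple) and len(spec) == 2:
        kind, param = spec
        if kind == "fixed":
            if int(param) < 1:
                raise ConfigurationError("variants_per_gene must be >= 1")
            return np.full(config.n_genes, int(param))
        if kind == "poisson":
            return 1 + rng.poisson(max(param - 1.0, 0.0), size=config.n_genes)
    raise ConfigurationError(f"invalid variants_per_gene spec: {spec!r}")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a different base)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def gen_transcriptome(config: SimulationConfig
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcript sequences plus a variant table.

    Returns ``(sequences, variants)`` where ``sequences`` maps variant ids
    (``comp<i>_c0_seq<j>``) to ACGT strings and ``variants`` lists
    ``gene_id, variant_id, length``.
    """
    rng = config.rng(STAGE_TRANSCRIPTOME)
    n_variants = _variant_counts(config, rng)
    sequences: dict[str, str] = {}
    rows = []
    for i in range(config.n_genes):
        gene = f"comp{i}_c0"
        length = max(config.min_length,
                     int(round(rng.normal(config.length_mean, config.length_sd))))
        base = rng.choice(_BASES, size=length)
        for j in range(n_variants[i]):
            vid = f"{gene}_seq{j + 1}"
            seq = base if j == 0 else _mutate(base, config.variant_divergence, rng)
            sequences[vid] = "".join(seq)
            rows.append((gene, vid, length))
    variants = pd.DataFrame(rows, columns=["gene_id", "variant_id", "length"])
    return sequences, variants


def gen_probesets(transcriptome: Mapping[str, str], config: SimulationConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A probe library with per-probe ground truth.

    On-target probesets copy ``probes_per_set`` windows from one transcript
    and mutate each base with probability ``probe_divergence_rate`` (each
    substitution is a guaranteed mismatch, so the truth mismatch count is
    exact). A fraction ``off_target_fraction`` of probesets is pure random
    sequence — the expected negative set. Transcripts shorter than the probe
    are skipped with a warning.

    Returns ``(library, truth)``; ``truth`` has one row per probe with
    ``probeset_id, probe_id, on_target, target_variant, target_gene, start,
    mismatches``.
    """
    rng = config.rng(STAGE_PROBES)
    plen = config.probe_length
    eligible = [vid for vid, seq in transcriptome.items() if len(seq) >= plen]
    skipped = [vid for vid in transcriptome if len(transcriptome[vid]) < plen]
    if skipped:
        warnings.warn(f"{len(skipped)} transcripts shorter than {plen} bp skipped")
    if not eligible and config.off_target_fraction < 1:
        raise ConfigurationError("no transcript is long enough to source probes")
    n_off = int(round(config.off_target_fraction * config.n_probesets))
    lib_rows, truth_rows = [], []
    for s in range(config.n_probesets):
        probeset = f"ps{s:05d}"
        off_target = s < n_off
        target = None if off_target else eligible[rng.integers(len(eligible))]
        for p in range(config.probes_per_set):
            probe_id = f"{probeset}_p{p:02d}"
            if off_target:
                seq = "".join(rng.choice(_BASES, size=plen))
                truth_rows.append((probeset, probe_id, False, None, None, -1, -1))
            else:
                tseq = transcriptome[target]
                start = int(rng.integers(len(tseq) - plen + 1))
                window = np.array(list(tseq[start:start + plen]))
                mutated = _mutate(window, config.probe_divergence_rate, rng)
                mismatches = int((mutated != window).sum())
                seq = "".join(mutated)
                truth_rows.append((probeset, probe_id, True, target,
                                   variant_gene(target, warn=False), start, mismatches))
            lib_rows.append((probeset, probe_id, seq))
    library = pd.DataFrame(lib_rows, columns=["probeset_id", "probe_id", "sequence"])
    truth = pd.DataFrame(truth_rows, columns=[
        "probeset_id", "probe_id", "on_target", "target_variant", "target_gene",
        "start", "mismatches"])
    return library, truth


def gen_truth(config: SimulationConfig, genes: Sequence[str] | None = None
              ) -> TruthTable:
    """Expression ground truth: expressed sets, markers, fold-change matrix.

    Each gene is silent in any given cell type with probability
    ``silent_fraction``; a ``de_fraction`` of genes are markers of one cell
    type (round-robin over cell types), forced on there with a
    ``fold_change``-fold elevated mean.
    """
    rng = config.rng(STAGE_TRUTH)
    if genes is None:
        genes = [f"comp{i}_c0" for i in range(config.n_genes)]
    genes = list(genes)
    samples = list(config.samples)
    n = len(genes)
    n_markers = int(round(config.de_fraction * n))
    marker_idx = rng.choice(n, size=n_markers, replace=False)
    markers = {genes[g]: samples[j % len(samples)]
               for j, g in enumerate(sorted(marker_idx))}
    fold = pd.DataFrame(1.0, index=genes, columns=samples)
    expressed_in: dict[str, set[str]] = {}
    for gene in genes:
        on = {s for s in samples if rng.random() >= config.silent_fraction}
        focal = markers.get(gene)
        if focal is not None:
            on.add(focal)
            fold.at[gene, focal] = config.fold_change
        expressed_in[gene] = on
    return TruthTable(genes=genes, samples=samples, expressed_in=expressed_in,
                      fold_change=fold, markers=markers)


def gen_array_intensities(library: pd.DataFrame, probe_truth: pd.DataFrame,
                          expressed_by_array: Mapping[str, set[str]],
                          config: SimulationConfig) -> pd.DataFrame:
    """Probe-level linear-scale intensities, one column per array.

    A probe draws its log2 intensity from the signal distribution when its
    probeset is on-target and the target gene is expressed on that array,
    otherwise from the background distribution; every probe additionally has
    a fixed additive affinity effect (mean 0) so median-polish summarization
    has structure to remove.
    """
    rng = config.rng(STAGE_INTENSITIES)
    probe_gene = dict(zip(probe_truth["probe_id"], probe_truth["target_gene"]))
    probes = list(library["probe_id"])
    genes = [probe_gene.get(p) for p in probes]
    effects = rng.normal(0.0, config.probe_effect_sd, size=len(probes))
    data = {}
    for array, expressed in expressed_by_array.items():
        hot = np.array([g is not None and g in expressed for g in genes])
        mu = np.where(hot, config.signal_mean, config.background_mean)
        sd = np.where(hot, config.signal_sd, config.background_sd)
        data[array] = 2.0 ** (rng.normal(mu, sd) + effects)
    return pd.DataFrame(data, index=pd.Index(probes, name="probe_id"))


def nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator
              ) -> np.ndarray:
    """Negative-binomial draws with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ConfigurationError("dispersion must be nonnegative")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def gen_counts(truth: TruthTable, config: SimulationConfig,
               variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """A genes x samples (or variants x samples) count table.

    Per-gene baseline means are log-normal around ``baseline_mean``; the mean
    in a sample is baseline x fold_change, zeroed where the gene is silent.
    When ``library_sizes`` is set, column means are rescaled so expected
    column sums match it. When ``variants`` is given, each gene's mean is
    split uniformly across its variants and the table is variant-keyed.
    """
    rng = config.rng(STAGE_COUNTS)
    genes = truth.genes
    if config.baseline_sigma == 0:
        base = np.full(len(genes), config.baseline_mean)
    else:
        sigma = config.baseline_sigma
        base = rng.lognormal(np.log(config.baseline_mean) - sigma ** 2 / 2, sigma,
                             size=len(genes))
    samples = truth.samples
    mean = np.zeros((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        on = np.array([sample in truth.expressed_in[g] for g in genes])
        mean[:, j] = base * truth.fold_change[sample].to_numpy() * on
    if config.library_sizes is not None:
        sizes = list(config.library_sizes)
        if len(sizes) != len(samples) or any(s <= 0 for s in sizes):
            raise ConfigurationError("library_sizes must give one positive size "
                                     "per sample")
        col = mean.sum(axis=0)
        mean = mean * (np.array(sizes, dtype=float) / np.where(col > 0, col, 1.0))
    index: list[str] = genes
    if variants is not None:
        split_rows, index = [], []
        for g, gene in enumerate(genes):
            vids = list(variants.loc[variants["gene_id"] == gene, "variant_id"])
            if not vids:
                vids = [gene]
            for vid in vids:
                split_rows.append(mean[g] / len(vids))
                index.append(vid)
        mean = np.array(split_rows)
    counts = nb_sample(mean, config.dispersion, rng)
    return pd.DataFrame(counts, index=pd.Index(index, name="gene"), columns=samples)


def gen_annotations(genes: Sequence[str], n_terms: int = 40, dag_depth: int = 4,
                    n_families: int = 15, seed: int = 42,
                    mean_terms_per_gene: float = 2.0,
                    family_size_range: tuple[int, int] = (5, 30)
                    ) -> tuple[list[tuple[str, str]], dict[str, set[str]],
                               dict[str, set[str]]]:
    """A rooted is_a DAG, direct gene->term annotations, and a family table.

    The DAG has a single root ``T0000``; every other term gets a depth in
    ``1..dag_depth`` and one or two parents from the level above, so
    acyclicity and the single root are guaranteed by construction.
    Annotations are direct only (propagation is a pipeline stage); a gene may
    belong to several families.
    """
    if dag_depth < 1:
        raise ConfigurationError("dag_depth must be >= 1")
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    rng = np.random.default_rng([int(seed) % (2 ** 31), STAGE_ANNOTATIONS])
    terms = [f"T{i:04d}" for i in range(n_terms)]
    levels: dict[int, list[str]] = {0: [terms[0]]}
    edges: list[tuple[str, str]] = []
    for i, term in enumerate(terms[1:], start=1):
        depth = min(1 + (i - 1) % dag_depth, dag_depth) if i <= dag_depth else \
            int(rng.integers(1, dag_depth + 1))
        while depth - 1 not in levels:
            depth -= 1
        levels.setdefault(depth, []).append(term)
        parents = levels[depth - 1]
        chosen = [parents[int(rng.integers(len(parents)))]]
        if len(parents) > 1 and rng.random() < 0.3:
            extra = parents[int(rng.integers(len(parents)))]
            if extra not in chosen:
                chosen.append(extra)
        for parent in chosen:
            edges.append((term, parent))
    gene2term: dict[str, set[str]] = {}
    non_root = terms[1:] if n_terms > 1 else terms
    for gene in genes:
        k = 1 + rng.poisson(max(mean_terms_per_gene - 1.0, 0.0))
        k = min(k, len(non_root))
        picked = rng.choice(len(non_root), size=k, replace=False)
        gene2term[gene] = {non_root[i] for i in picked}
    families: dict[str, set[str]] = {}
    lo, hi = family_size_range
    for f in range(n_families):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(genes))
        picked = rng.choice(len(genes), size=size, replace=False)
        families[f"FAM{f:03d}"] = {genes[i] for i in picked}
    return edges, gene2term, families


def gen_homolog_psl(transcriptome_a: Mapping[str, str],
                    transcriptome_b: Mapping[str, str],
                    divergence: float = 0.05, pair_fraction: float = 0.9,
                    decoy_fraction: float = 0.5, seed: int = 42
                    ) -> tuple[list[PslRecord], pd.DataFrame]:
    """Synthetic cross-species alignments with a known true pairing.

    Query genes (one representative variant each) are paired index-wise with
    target genes; a ``pair_fraction`` of query genes gets a true single-block
    alignment with ``divergence`` mismatch fraction, and a ``decoy_fraction``
    of those additionally gets a decoy record to a *different* target gene at
    roughly half the true score. Records satisfy the PSL invariants
    (block sizes sum to matches + misMatches).

    Returns ``(records, truth)`` with truth columns ``query_gene,
    target_gene`` (NA for unpaired genes).
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), STAGE_PSL])

    def representatives(tr: Mapping[str, str]) -> dict[str, str]:
        reps: dict[str, str] = {}
        for vid in tr:
            gene = variant_gene(vid, warn=False)
            reps.setdefault(gene, vid)
        return reps

    reps_a = representatives(transcriptome_a)
    reps_b = representatives(transcriptome_b)
    genes_a, genes_b = list(reps_a), list(reps_b)
    n_pairs = min(len(genes_a), len(genes_b))
    records: list[PslRecord] = []
    truth_rows = []

    def make_record(qvid: str, tvid: str, length: int, matches: int) -> PslRecord:
        mis = length - matches
        return PslRecord(
            matches=matches, misMatches=mis, repMatches=0, nCount=0,
            qNumInsert=0, qBaseInsert=0, tNumInsert=0, tBaseInsert=0,
            strand="+", qName=qvid, qSize=len(transcriptome_a[qvid]),
            qStart=0, qEnd=length, tName=tvid, tSize=len(transcriptome_b[tvid]),
            tStart=0, tEnd=length, blockCount=1, blockSizes=f"{length},",
            qStarts="0,", tStarts="0,")

    for i, qgene in enumerate(genes_a):
        if i >= n_pairs or rng.random() >= pair_fraction:
            truth_rows.append((qgene, pd.NA))
            continue
        tgene = genes_b[i]
        qvid, tvid = reps_a[qgene], reps_b[tgene]
        length = min(len(transcriptome_a[qvid]), len(transcriptome_b[tvid]))
        matches = int(round(length * (1.0 - divergence)))
        records.append(make_record(qvid, tvid, length, matches))
        truth_rows.append((qgene, tgene))
        if len(genes_b) > 1 and rng.random() < decoy_fraction:
            true_score = matches - (length - matches)
            while True:
                other = genes_b[int(rng.integers(len(genes_b)))]
                if other != tgene:
                    break
            ovid = reps_b[other]
            dlen = min(length, len(transcriptome_b[ovid]))
            # choose matches so the decoy score is about half the true score
            dmatches = int(round((true_score / 2.0 + dlen) / 2.0))
            dmatches = min(max(dmatches, 0), dlen)
            records.append(make_record(qvid, ovid, dlen, dmatches))
    truth = pd.DataFrame(truth_rows, columns=["query_gene", "target_gene"])
    return records, truth


def derive_species_b(transcriptome_a: Mapping[str, str], config: SimulationConfig,
                     prefix: str = "at") -> dict[str, str]:
    """A diverged partner transcriptome: one gene per query gene, renamed."""
    rng = config.rng(STAGE_PSL + 1)
    out: dict[str, str] = {}
    seen: set[str] = set()
    for i, (vid, seq) in enumerate(transcriptome_a.items()):
        gene = variant_gene(vid, warn=False)
        if gene in seen:
            continue
        seen.add(gene)
        arr = _mutate(np.array(list(seq)), 0.05, rng)
        out[f"comp{90000 + i}_c0_seq1"] = "".join(arr)
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
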