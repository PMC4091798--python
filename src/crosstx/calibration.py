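"""Self-contained calibration experiments on synthetic fixtures.

Each function sets up a ground-truthed simulation, runs the relevant
pipeline stages end to end, and measures an operating characteristic of the
method: presence-call calibration and power, aligner/assignment recovery,
exact-test type-I error, NOISeq detection of planted markers, and the
detectability of a planted overrepresented family. They are used both by the
test suite and by the reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import diffexpr, enrichment
from .homology import assign_homologues
from .presence import panp_pvalues, rma_lite
from .probes import align_library, classify_negative
from .simulate import (SimulationConfig, derive_species_b, gen_counts,
                       gen_homolog_psl, gen_probesets, gen_transcriptome,
                       gen_truth, gen_array_intensities)


def _background_probesets(prefix: str, count: int, probes_per_set: int = 11):
    lib_rows, truth_rows = [], []
    for s in range(count):
        probeset = f"{prefix}{s:05d}"
        for p in range(probes_per_set):
            probe = f"{probeset}_p{p:02d}"
            lib_rows.append((probeset, probe, "A" * 25))
            truth_rows.append((probeset, probe, False, None, None, -1, -1))
    return lib_rows, truth_rows


def panp_calibration_run(n_neg: int = 10_000, n_null: int = 5000,
                         n_sig: int = 500, seed: int = 42) -> dict:
    """Calibration and power of the negative-probeset presence call.

    Negative and null probesets both measure pure background (the null set is
    simply not told to the caller); signal probesets interrogate genes whose
    intensity sits ``signal_mean - background_mean`` (default three background
    SD) higher. All probe-level intensities are summarized (log2, quantile
    normalization, median polish over 11 probes) before p-values are taken.
    """
    config = SimulationConfig(seed=seed)
    lib_rows, truth_rows = _background_probesets("neg", n_neg)
    more = _background_probesets("null", n_null)
    lib_rows += more[0]
    truth_rows += more[1]
    sig_genes = set()
    for s in range(n_sig):
        probeset = f"sig{s:05d}"
        gene = f"gene{s:05d}"
        sig_genes.add(gene)
        for p in range(11):
            probe = f"{probeset}_p{p:02d}"
            lib_rows.append((probeset, probe, "A" * 25))
            truth_rows.append((probeset, probe, True, gene + "_v1", gene, 0, 0))
    library = pd.DataFrame(lib_rows, columns=["probeset_id", "probe_id",
                                              "sequence"])
    probe_truth = pd.DataFrame(truth_rows, columns=[
        "probeset_id", "probe_id", "on_target", "target_variant", "target_gene",
        "start", "mismatches"])
    intensities = gen_array_intensities(
        library, probe_truth, {"a1": sig_genes, "a2": sig_genes}, config)
    expression = rma_lite(intensities, library)
    negatives = {f"neg{s:05d}" for s in range(n_neg)}
    pvals = panp_pvalues(expression, negatives)["a1"]
    null_p = pvals.loc[[f"null{s:05d}" for s in range(n_null)]].to_numpy()
    sig_p = pvals.loc[[f"sig{s:05d}" for s in range(n_sig)]].to_numpy()
    return {
        "null_p": null_p,
        "null_p_rate": float((null_p <= 0.02).mean()),
        "signal_p_rate": float((sig_p <= 0.02).mean()),
        "ks_uniform_p": float(kstest(null_p, "uniform").pvalue),
    }


def aligner_agreement_run(n_probesets: int = 19, n_genes: int = 50,
                          length_mean: float = 1000.0, seed: int = 42) -> dict:
    """Fraction of probes on which the seed-and-filter aligner reproduces a
    naive both-strand Hamming scan exactly (hit-for-hit)."""
    config = SimulationConfig(seed=seed, n_genes=n_genes,
                              length_mean=length_mean, length_sd=0.0,
                              n_probesets=n_probesets,
                              off_target_fraction=0.3,
                              probe_divergence_rate=0.08)
    transcriptome, _ = gen_transcriptome(config)
    library, _ = gen_probesets(transcriptome, config)
    alignments = align_library(library, transcriptome, max_mismatches=3)
    by_probe = {
        pid: sorted((r.target_id, int(r.start), r.strand, int(r.mismatches))
                    for r in alignments[alignments["probe_id"] == pid].itertuples())
        for pid in library["probe_id"]}
    agree = 0
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    arrays = {tid: np.frombuffer(seq.encode(), np.uint8)
              for tid, seq in transcriptome.items()}
    for pid, seq in zip(library["probe_id"], library["sequence"]):
        expected = []
        rc = "".join(comp[b] for b in reversed(seq))
        for strand, query in (("+", seq), ("-", rc)):
            q = np.frombuffer(query.encode(), np.uint8)
            for tid, t in arrays.items():
                if len(t) < 25:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(t, 25)
                mm = (win != q).sum(axis=1)
                for start in np.flatnonzero(mm <= 3):
                    expected.append((tid, int(start), strand, int(mm[start])))
        agree += by_probe[pid] == sorted(expected)
    negatives = classify_negative(library, alignments)
    return {"probe_agreement_rate": agree / len(library),
            "n_negative_probesets": len(negatives)}


def homolog_recovery_run(n_genes: int = 150, divergence: float = 0.05,
                         seed: int = 42) -> dict:
    """True-pair recovery of the score-sum argmax under half-score decoys."""
    config = SimulationConfig(seed=seed, n_genes=n_genes, length_mean=600.0,
                              length_sd=100.0)
    tr_a, _ = gen_transcriptome(config)
    tr_b = derive_species_b(tr_a, config)
    records, truth = gen_homolog_psl(tr_a, tr_b, divergence=divergence,
                                     pair_fraction=1.0, decoy_fraction=0.5,
                                     seed=seed)
    out = assign_homologues(records)
    got = dict(zip(out["query_gene"], out["target_gene"]))
    paired = [(q, t) for q, t in zip(truth["query_gene"], truth["target_gene"])
              if not pd.isna(t)]
    recovered = sum(got.get(q) == t for q, t in paired)
    return {"recovery_rate": recovered / len(paired), "n_pairs": len(paired)}


def nb_type1_run(n_genes: int = 2000, mu: float = 100.0, dispersion: float = 0.64,
                 alpha: float = 0.05, seed: int = 42) -> dict:
    """Empirical type-I error of the exact NB test under its own null."""
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion
    p_nb = r / (r + mu)
    x1 = rng.negative_binomial(r, p_nb, size=n_genes)
    x2 = rng.negative_binomial(r, p_nb, size=n_genes)
    pvals = np.array([diffexpr.exact_nb_test(a, b, 1.0, 1.0, dispersion)
                      for a, b in zip(x1, x2)])
    return {"type1_rate": float((pvals <= alpha).mean()), "n": n_genes}


def noiseq_recall_run(n_genes: int = 2000, de_fraction: float = 0.1,
                      fold: float = 4.0, q: float = 0.9, seed: int = 42) -> dict:
    """Recall/precision of NOISeq-sim enrichment on planted focal markers."""
    config = SimulationConfig(seed=seed, n_genes=n_genes, de_fraction=de_fraction,
                              fold_change=fold, silent_fraction=0.0,
                              baseline_sigma=1.0)
    truth = gen_truth(config)
    counts = gen_counts(truth, config)
    results = {}
    for other in ("egg", "central", "synergid"):
        res, _ = diffexpr.noiseq_sim(counts, "aic", other, seed=seed)
        results[other] = res
    enriched = diffexpr.noiseq_enriched(results, q=q)
    markers = {g for g, s in truth.markers.items() if s == "aic"}
    recall = len(enriched & markers) / len(markers) if markers else float("nan")
    precision = len(enriched & markers) / len(enriched) if enriched else float("nan")
    return {"recall": recall, "precision": precision,
            "n_enriched": len(enriched), "n_markers": len(markers)}


def null_noiseq_rate_run(n_genes: int = 1000, q: float = 0.9,
                         seed: int = 42) -> dict:
    """Fraction of genes called DE by NOISeq-sim when nothing is DE."""
    config = SimulationConfig(seed=seed, n_genes=n_genes, de_fraction=0.0,
                              silent_fraction=0.0)
    truth = gen_truth(config)
    counts = gen_counts(truth, config)
    res, _ = diffexpr.noiseq_sim(counts, "aic", "egg", seed=seed)
    return {"null_de_rate": float((res["prob"] > q).mean()), "n": n_genes}


def planted_family_run(n_genes: int = 1000, family_size: int = 40,
                       overrep: float = 10.0, study_size: int = 100,
                       seed: int = 42) -> dict:
    """Two-sided Fisher p for a family planted ~10x overrepresented in a study set."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    family = set(genes[:family_size])
    base_rate = study_size / n_genes
    in_rate = min(overrep * base_rate, 1.0)
    study = {g for g in genes
             if rng.random() < (in_rate if g in family else base_rate)}
    out = enrichment.fisher_two_sided(study, {"planted": family}, set(genes))
    return {"planted_family_p": float(out.loc[0, "p_value"]),
            "overlap": int(out.loc[0, "significant"]),
            "expected": float(out.loc[0, "expected"])}
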