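"""End-to-end orchestration of the synthetic-fixture analysis pipeline.

``run_pipeline`` drives every stage in dependency order on generated
fixtures: transcriptome and probe simulation, k-mismatch probe alignment and
negative-set derivation, intensity summarization and presence calls,
homologue assignment from synthetic PSL, count aggregation and
normalization, replicate-free differential expression (both routes),
cross-platform evidence and overlap counts, term/family enrichment, and the
heatmap-path clustering order. Everything is written as plain-text tables
under the output directory, and a JSON report collects the summary counts
together with the resolved configuration and its hash, so an identical
configuration and seed re-emit byte-identical outputs.

``audit_report`` re-derives every reported count from the emitted files and
flags any mismatch — the report is only trusted if it is recomputable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, counts as counts_mod, diffexpr, enrichment, evidence, io, presence, probes
from .homology import assign_homologues, homology_dict, read_psl, write_psl
from .simulate import (SimulationConfig, derive_species_b, gen_annotations,
                       gen_array_intensities, gen_counts, gen_homolog_psl,
                       gen_probesets, gen_transcriptome, gen_truth)

logger = logging.getLogger("crosstx")


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_probesets=200, off_target_fraction=0.3))
    max_mismatches: int = 3
    p_present: float = 0.02
    p_marginal: float = 0.04
    min_negatives: int = 50
    min_reads: int = 5
    min_total_len: int = 100
    q: float = 0.9
    fdr_cut: float = 0.05
    raw_cut: float = 0.001
    focal: str = "aic"
    special_pair: tuple[str, str] = ("egg", "central")
    elim_cutoff: float = 0.01
    n_heatmap_genes: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "library_sizes" in sim_raw and sim_raw["library_sizes"] is not None:
            sim_raw["library_sizes"] = tuple(sim_raw["library_sizes"])
        if "samples" in sim_raw:
            sim_raw["samples"] = tuple(sim_raw["samples"])
        if "special_pair" in raw:
            raw["special_pair"] = tuple(raw["special_pair"])
        return cls(sim=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _array_design(samples) -> pd.DataFrame:
    """Array/RNA-seq sample inventory: two arrays for the first (founder)
    cell type, one for each other, plus one RNA-seq library per cell type."""
    rows = []
    for i, cell in enumerate(samples):
        n_arrays = 2 if i == 0 else 1
        for a in range(1, n_arrays + 1):
            rows.append((f"{cell}_array{a}", "array", cell))
        rows.append((cell, "rnaseq", cell))
    return pd.DataFrame(rows, columns=["sample", "platform", "cell_type"])


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns (and writes) the report bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    summary: dict = {}
    manifest: list[str] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.append(name)
        return path

    logger.info("stage: simulate transcriptome")
    transcriptome, variants = gen_transcriptome(sim)
    emit("transcriptome.fasta", lambda p: io.write_fasta(transcriptome, p))
    emit("variants.tsv", lambda p: variants.to_csv(p, sep="\t", index=False))

    logger.info("stage: simulate probes and align")
    library, probe_truth = gen_probesets(transcriptome, sim)
    emit("probes.tsv", lambda p: io.write_probe_library(library, p))
    emit("probe_truth.tsv", lambda p: probe_truth.to_csv(p, sep="\t", index=False))
    alignments = probes.align_library(library, transcriptome,
                                      max_mismatches=config.max_mismatches,
                                      probe_length=sim.probe_length)
    emit("alignments.tsv", lambda p: probes.write_alignments(alignments, p))
    negatives = probes.classify_negative(library, alignments)
    emit("negative_probesets.txt", lambda p: io.write_gene_set(negatives, p))
    summary["n_negative_probesets"] = len(negatives)

    logger.info("stage: truth, intensities, presence calls")
    truth = gen_truth(sim)
    design = _array_design(truth.samples)
    emit("design.tsv", lambda p: design.to_csv(p, sep="\t", index=False))
    arrays = design.loc[design["platform"] == "array", ["sample", "cell_type"]]
    expressed_by_array = {
        row["sample"]: {g for g in truth.genes
                        if row["cell_type"] in truth.expressed_in[g]}
        for _, row in arrays.iterrows()}
    intensities = gen_array_intensities(library, probe_truth, expressed_by_array, sim)
    emit("intensities.tsv", lambda p: io.write_matrix(intensities, p, "probe_id"))
    expression = presence.rma_lite(intensities, library)
    emit("expression.tsv", lambda p: io.write_matrix(expression, p, "probeset_id"))
    pvals = presence.panp_pvalues(expression, negatives,
                                  min_negatives=config.min_negatives)
    emit("panp_p.tsv", lambda p: io.write_matrix(pvals, p, "probeset_id"))
    calls = presence.pa_calls(pvals, config.p_present, config.p_marginal)
    calls_tall = presence.calls_long(pvals, calls)
    emit("calls.tsv", lambda p: calls_tall.to_csv(p, sep="\t", index=False))
    summary["present_per_array"] = {
        a: int((calls[a] == "P").sum()) for a in calls.columns}

    logger.info("stage: homologues")
    species_b = derive_species_b(transcriptome, sim)
    emit("species_b.fasta", lambda p: io.write_fasta(species_b, p))
    psl_records, psl_truth = gen_homolog_psl(transcriptome, species_b,
                                             seed=sim.seed)
    emit("homologs.psl", lambda p: write_psl(psl_records, p, header=True))
    emit("homolog_truth.tsv", lambda p: psl_truth.to_csv(p, sep="\t", index=False))
    assignment = assign_homologues(read_psl(out / "homologs.psl"),
                                   min_total_len=config.min_total_len)
    emit("homologs.tsv", lambda p: assignment.to_csv(p, sep="\t", index=False))
    homology = homology_dict(assignment)
    summary["n_homologues_assigned"] = int(assignment["target_gene"].notna().sum())

    logger.info("stage: counts and normalization")
    variant_counts = gen_counts(truth, sim, variants=variants)
    emit("counts_variants.tsv", lambda p: io.write_matrix(variant_counts, p, "variant_id"))
    gene_counts = counts_mod.gene_counts(variant_counts)
    emit("counts_genes.tsv", lambda p: io.write_matrix(gene_counts, p, "gene"))
    expressed = counts_mod.expressed_genes(gene_counts, min_reads=config.min_reads)
    summary["expressed_per_sample"] = {s: len(g) for s, g in expressed.items()}
    tmm = counts_mod.tmm_factors(gene_counts)
    emit("factors_tmm.tsv", lambda p: counts_mod.factors_frame(tmm, "tmm")
         .to_csv(p, sep="\t", index=False))
    size_factors = counts_mod.size_factors_median_ratio(gene_counts)
    emit("factors_median_ratio.tsv",
         lambda p: counts_mod.factors_frame(size_factors, "median_ratio")
         .to_csv(p, sep="\t", index=False))

    logger.info("stage: differential expression")
    others = [s for s in truth.samples if s != config.focal]
    noiseq_results = {}
    for other in others:
        res, _ = diffexpr.noiseq_sim(gene_counts, config.focal, other,
                                     norm_factors=tmm, seed=sim.seed)
        noiseq_results[other] = res
        emit(f"noiseq_{config.focal}_vs_{other}.tsv",
             lambda p, r=res: r.to_csv(p, sep="\t"))
    noiseq_set = diffexpr.noiseq_enriched(noiseq_results, q=config.q)
    emit("noiseq_enriched.txt", lambda p: io.write_gene_set(noiseq_set, p))
    summary["n_noiseq_enriched"] = len(noiseq_set)

    pairwise = {}
    samples = list(truth.samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            res = diffexpr.exact_nb_contrast(gene_counts, a, b,
                                             dispersion=sim.dispersion,
                                             norm_factors=tmm)
            pairwise[(a, b)] = res
            emit(f"exact_{a}_vs_{b}.tsv", lambda p, r=res: r.to_csv(p, sep="\t"))
    exact_set, de_union = diffexpr.exact_test_enriched(
        pairwise, config.focal, fdr_cut=config.fdr_cut, raw_cut=config.raw_cut,
        special_pair=config.special_pair)
    emit("exact_enriched.txt", lambda p: io.write_gene_set(exact_set, p))
    emit("exact_de_union.txt", lambda p: io.write_gene_set(de_union, p))
    summary["n_exact_enriched"] = len(exact_set)
    summary["n_exact_de_union"] = len(de_union)

    logger.info("stage: evidence and overlaps")
    probeset_gene = dict(zip(probe_truth["probeset_id"], probe_truth["target_gene"]))
    p_rows = []
    for array in calls.columns:
        genes_p = {probeset_gene.get(ps) for ps in calls.index
                   if calls.at[ps, array] == "P"}
        genes_p.discard(None)
        for g in sorted(genes_p):
            p_rows.append((g, array, 0.0, "P"))
    gene_calls = pd.DataFrame(p_rows, columns=["probeset", "array", "p", "call"])
    evidence_a = evidence.build_evidence(gene_calls, expressed, None, design)
    emit("evidence.tsv", lambda p: evidence_a.to_csv(p, sep="\t"))

    # partner-species expressed sets, derived from the true pairing with noise
    rng = np.random.default_rng([sim.seed % (2 ** 31), 9])
    pairing = dict(zip(psl_truth["query_gene"], psl_truth["target_gene"]))
    species_b_expressed: dict[str, set[str]] = {}
    for cell in truth.samples:
        genes_b = set()
        for gene in truth.genes:
            partner = pairing.get(gene)
            if pd.isna(partner):
                continue
            on = cell in truth.expressed_in[gene]
            if rng.random() < 0.1:
                on = not on
            if on:
                genes_b.add(gene)  # anchored on species-A ids via the true pairing
        species_b_expressed[cell] = genes_b
        emit(f"speciesB_expressed_{cell}.txt",
             lambda p, g=genes_b: io.write_gene_set(g, p))

    focal_cell = config.focal
    rule_a = evidence.get_rule("aic_exclusive")
    set_a = evidence.expressed_under(evidence_a, focal_cell, rule_a)
    set_b = species_b_expressed[focal_cell]
    a_only, b_only, shared = set_a - set_b, set_b - set_a, set_a & set_b
    emit("exclusive_a_only.txt", lambda p: io.write_gene_set(a_only, p))
    emit("exclusive_b_only.txt", lambda p: io.write_gene_set(b_only, p))
    emit("exclusive_shared.txt", lambda p: io.write_gene_set(shared, p))
    summary["exclusive"] = {"a_only": len(a_only), "b_only": len(b_only),
                            "shared": len(shared)}

    array_set = evidence.expressed_under(evidence_a, focal_cell, "array_any")
    venn = evidence.overlap_counts({"array": array_set,
                                    "rnaseq": expressed[focal_cell],
                                    "partner": set_b})
    summary["venn_focal"] = venn
    emit("venn_counts.tsv", lambda p: pd.DataFrame(
        sorted(venn.items()), columns=["region", "count"]).to_csv(p, sep="\t", index=False))

    focal_arrays = design[(design["cell_type"] == focal_cell)
                          & (design["platform"] == "array")]["sample"]
    per_sample = {a: {probeset_gene.get(ps) for ps in calls.index
                      if calls.at[ps, a] == "P"} - {None}
                  for a in focal_arrays}
    per_sample[focal_cell] = expressed[focal_cell]
    multi = evidence.multi_sample_expressed(per_sample, min_samples=2)
    emit("multi_sample_expressed.txt", lambda p: io.write_gene_set(multi, p))
    summary["n_multi_sample_expressed"] = len(multi)

    logger.info("stage: enrichment")
    edges, gene2term, families = gen_annotations(truth.genes, seed=sim.seed)
    emit("ontology_edges.tsv", lambda p: io.write_dag_edges(edges, p))
    emit("gene2term.tsv", lambda p: io.write_gene2term(gene2term, p))
    emit("families.tsv", lambda p: io.write_families(families, p))
    dag = enrichment.OntologyDag(edges, terms={t for e in edges for t in e}
                                 | {"T0000"})
    annotations = enrichment.propagate_annotations(dag, gene2term)
    universe = enrichment.annotated_universe(annotations)
    study = noiseq_set & universe
    go_classic = enrichment.fisher_classic(study, annotations, universe)
    emit("enrichment_go_classic.tsv",
         lambda p: go_classic.to_csv(p, sep="\t", index=False))
    go_elim = enrichment.go_elim(dag, study, annotations, universe,
                                 elim_cutoff=config.elim_cutoff)
    emit("enrichment_go_elim.tsv", lambda p: go_elim.to_csv(p, sep="\t", index=False))
    fam_universe = set(truth.genes)
    fam_study = (exact_set if exact_set else noiseq_set) & fam_universe
    fam = enrichment.fisher_two_sided(fam_study, families, fam_universe)
    emit("enrichment_families.tsv", lambda p: fam.to_csv(p, sep="\t", index=False))
    summary["min_go_p"] = float(go_classic["p_value"].min()) if len(go_classic) else 1.0

    logger.info("stage: heatmap path")
    scaled = cluster.row_scale_log2(gene_counts, size_factors)
    variances = scaled.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable")
    top_genes = sorted(top.index[:config.n_heatmap_genes])
    _, leaf_order = cluster.hcluster(scaled.loc[top_genes])
    emit("heatmap_leaf_order.txt",
         lambda p: p.write_text("".join(f"{g}\n" for g in leaf_order)))

    report = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": sim.seed,
        "summary": summary,
        "manifest": sorted(manifest),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=str) + "\n")
    return report


def audit_report(outdir: str | Path) -> dict[str, bool]:
    """Recompute every summary count from the emitted files.

    Returns a mapping check-name -> passed; the report is self-consistent
    iff all values are True.
    """
    out = Path(outdir)
    report = json.loads((out / "report.json").read_text())
    summary = report["summary"]
    checks: dict[str, bool] = {}

    negatives = io.read_gene_set(out / "negative_probesets.txt")
    checks["negative_count"] = len(negatives) == summary["n_negative_probesets"]

    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    present = calls[calls["call"] == "P"].groupby("array")["probeset"].nunique()
    checks["present_per_array"] = all(
        int(present.get(a, 0)) == n for a, n in summary["present_per_array"].items())

    gene_counts = io.read_matrix(out / "counts_genes.tsv")
    min_reads = report["config"]["min_reads"]
    checks["expressed_per_sample"] = all(
        int((gene_counts[s] >= min_reads).sum()) == n
        for s, n in summary["expressed_per_sample"].items())

    assignment = pd.read_csv(out / "homologs.tsv", sep="\t")
    checks["homologues_assigned"] = (
        int(assignment["target_gene"].notna().sum()) == summary["n_homologues_assigned"])

    checks["noiseq_enriched"] = (
        len(io.read_gene_set(out / "noiseq_enriched.txt")) == summary["n_noiseq_enriched"])
    checks["exact_enriched"] = (
        len(io.read_gene_set(out / "exact_enriched.txt")) == summary["n_exact_enriched"])
    checks["exact_de_union"] = (
        len(io.read_gene_set(out / "exact_de_union.txt")) == summary["n_exact_de_union"])

    a_only = io.read_gene_set(out / "exclusive_a_only.txt")
    b_only = io.read_gene_set(out / "exclusive_b_only.txt")
    shared = io.read_gene_set(out / "exclusive_shared.txt")
    excl = summary["exclusive"]
    checks["exclusive_sizes"] = (len(a_only) == excl["a_only"]
                                 and len(b_only) == excl["b_only"]
                                 and len(shared) == excl["shared"])
    checks["exclusive_partition"] = (not (a_only & b_only) and not (a_only & shared)
                                     and not (b_only & shared))

    venn = pd.read_csv(out / "venn_counts.tsv", sep="\t")
    checks["venn_matches"] = dict(zip(venn["region"], venn["count"])) == {
        k: v for k, v in summary["venn_focal"].items()}

    checks["multi_sample"] = (
        len(io.read_gene_set(out / "multi_sample_expressed.txt"))
        == summary["n_multi_sample_expressed"])

    go_classic = pd.read_csv(out / "enrichment_go_classic.tsv", sep="\t")
    if len(go_classic):
        checks["min_go_p"] = abs(float(go_classic["p_value"].min())
                                 - summary["min_go_p"]) < 1e-12
    return checks
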