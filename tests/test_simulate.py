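"""Generator determinism, moment checks, and configuration validation."""
import numpy as np
import pandas as pd
import pytest

from crosstx.simulate import (ConfigurationError, SimulationConfig, gen_annotations,
                              gen_array_intensities, gen_counts, gen_homolog_psl,
                              gen_probesets, gen_transcriptome, gen_truth,
                              derive_species_b, nb_sample)


class TestTranscriptome:
    def test_same_seed_identical_output(self, small_config):
        a, _ = gen_transcriptome(small_config)
        b, _ = gen_transcriptome(small_config)
        assert a == b

    def test_fixed_one_variant_gives_n_genes_sequences(self):
        config = SimulationConfig(seed=2, n_genes=17, variants_per_gene=1)
        sequences, variants = gen_transcriptome(config)
        assert len(sequences) == 17
        assert variants["gene_id"].nunique() == 17

    def test_id_convention(self, small_transcriptome):
        sequences, _ = small_transcriptome
        import re
        assert all(re.match(r"comp\d+_c\d+_seq\d+$", vid) for vid in sequences)

    def test_mean_length_within_three_se(self):
        config = SimulationConfig(seed=3, n_genes=100, length_mean=1000.0,
                                  length_sd=200.0, min_length=100)
        sequences, _ = gen_transcriptome(config)
        lengths = np.array([len(s) for s in sequences.values()])
        se = 200.0 / np.sqrt(100)
        assert abs(lengths.mean() - 1000.0) < 3 * se

    def test_invalid_distribution_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_transcriptome(SimulationConfig(variants_per_gene=("weird", 2)))
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0)


class TestProbesets:
    def test_zero_divergence_zero_mismatches(self, small_transcriptome):
        sequences, _ = small_transcriptome
        config = SimulationConfig(seed=4, n_probesets=20, off_target_fraction=0.0,
                                  probe_divergence_rate=0.0)
        _, truth = gen_probesets(sequences, config)
        assert (truth["mismatches"] == 0).all()

    def test_all_off_target_when_fraction_one(self, small_transcriptome):
        sequences, _ = small_transcriptome
        config = SimulationConfig(seed=4, n_probesets=10, off_target_fraction=1.0)
        _, truth = gen_probesets(sequences, config)
        assert (~truth["on_target"]).all()

    def test_mean_mismatch_count_matches_rate(self, small_transcriptome):
        sequences, _ = small_transcriptome
        config = SimulationConfig(seed=6, n_probesets=200, off_target_fraction=0.0,
                                  probe_divergence_rate=0.04)
        _, truth = gen_probesets(sequences, config)
        mm = truth["mismatches"].to_numpy()
        expected = 25 * 0.04
        se = np.sqrt(25 * 0.04 * 0.96 / len(mm))
        assert abs(mm.mean() - expected) < 3 * se

    def test_probes_are_25mers(self, small_probes):
        library, _ = small_probes
        assert library["sequence"].str.len().eq(25).all()


class TestIntensities:
    def test_deterministic_and_two_valued_when_degenerate(self, small_probes):
        library, truth = small_probes
        config = SimulationConfig(seed=5, background_sd=0.0, signal_sd=0.0,
                                  probe_effect_sd=0.0)
        expressed = {"a1": set(), "a2": {g for g in truth["target_gene"].dropna()}}
        m1 = gen_array_intensities(library, truth, expressed, config)
        m2 = gen_array_intensities(library, truth, expressed, config)
        assert m1.equals(m2)
        assert set(np.unique(m1.to_numpy())) <= {2.0 ** 6, 2.0 ** 9}
        assert (m1.to_numpy() > 0).all()

    def test_signal_below_background_warns(self):
        with pytest.warns(UserWarning, match="background"):
            SimulationConfig(signal_mean=5.0, background_mean=6.0)


class TestCounts:
    def test_poisson_limit_variance_near_mean(self):
        config = SimulationConfig(seed=8, n_genes=2000, dispersion=0.0,
                                  baseline_mean=100.0, baseline_sigma=0.0,
                                  silent_fraction=0.0, de_fraction=0.0)
        counts = gen_counts(gen_truth(config), config)
        x = counts["aic"].to_numpy()
        assert abs(x.var() / x.mean() - 1.0) < 0.15

    def test_nb_moments_at_fixed_dispersion(self):
        """Variance ~ mu + 0.64 mu^2 at mu = 100 over 2000 genes."""
        config = SimulationConfig(seed=9, n_genes=2000, dispersion=0.64,
                                  baseline_mean=100.0, baseline_sigma=0.0,
                                  silent_fraction=0.0, de_fraction=0.0)
        counts = gen_counts(gen_truth(config), config)
        x = counts["egg"].to_numpy(dtype=float)
        expected_var = 100.0 + 0.64 * 100.0 ** 2
        # SE of the sample variance for NB via the fourth central moment
        mu = 100.0
        phi = 0.64
        var = expected_var
        kurt_excess = 6 * phi + (1 + 6 * phi * mu * (1 + phi * mu)) / var
        se_var = var * np.sqrt((kurt_excess + 2) / 2000)
        assert abs(x.var(ddof=1) - expected_var) < 3 * se_var

    def test_library_size_scaling(self):
        config = SimulationConfig(seed=10, n_genes=500,
                                  library_sizes=(50_000, 60_000, 70_000, 80_000),
                                  silent_fraction=0.0)
        counts = gen_counts(gen_truth(config), config)
        sums = counts.sum().to_numpy(dtype=float)
        assert np.all(np.abs(sums / np.array([50_000, 60_000, 70_000, 80_000])
                             - 1.0) < 0.1)

    def test_negative_dispersion_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            nb_sample(np.array([10.0]), -0.5, rng)


class TestAnnotations:
    def test_single_term_star(self):
        edges, gene2term, _ = gen_annotations(["g1", "g2"], n_terms=1, seed=1)
        assert edges == []
        assert gene2term == {"g1": {"T0000"}, "g2": {"T0000"}}

    def test_depth_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_annotations(["g"], dag_depth=0)

    def test_families_are_gene_subsets(self):
        genes = [f"g{i}" for i in range(50)]
        _, _, families = gen_annotations(genes, n_families=8, seed=2)
        assert len(families) == 8
        for members in families.values():
            assert members <= set(genes)


class TestHomologPsl:
    def test_records_satisfy_psl_invariants(self, small_transcriptome,
                                            small_config):
        sequences, _ = small_transcriptome
        partner = derive_species_b(sequences, small_config)
        records, _ = gen_homolog_psl(sequences, partner, seed=1)
        for rec in records:
            rec.validate()

    def test_short_alignments_only_yield_no_homologue(self):
        from crosstx.homology import assign_homologues
        from test_homology import make_record
        out = assign_homologues([make_record(matches=60, mis=0)])
        assert pd.isna(out.loc[0, "target_gene"])


class TestTruth:
    def test_markers_expressed_in_focal_sample(self):
        config = SimulationConfig(seed=12, n_genes=100, de_fraction=0.2)
        truth = gen_truth(config)
        for gene, focal in truth.markers.items():
            assert focal in truth.expressed_in[gene]
            assert truth.fold_change.at[gene, focal] == config.fold_change

    def test_round_trip_through_writers(self, tmp_path, small_transcriptome,
                                        small_probes):
        from crosstx import io
        sequences, _ = small_transcriptome
        library, _ = small_probes
        io.write_fasta(sequences, tmp_path / "t.fasta")
        assert io.read_fasta(tmp_path / "t.fasta") == sequences
        io.write_probe_library(library, tmp_path / "p.tsv")
        assert io.read_probe_library(tmp_path / "p.tsv").equals(library)
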