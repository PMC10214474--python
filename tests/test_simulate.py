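import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboprof.errors import ConfigurationError
from riboprof.model import FOOTPRINT, MRNA
from riboprof.simulate import (PLANTABLE_FEATURES, SimulationConfig,
                               ground_truth_table, simulate_libraries,
                               simulate_transcriptome)
from riboprof.utr_features import find_pg4, find_uorfs, has_top_motif

from .oracles import brute_uorfs


class TestConfigValidation:
    def test_bad_ranges(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(utr5_length_range=(50, 20)).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(cds_length_range=(3, 9)).validate()

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(footprint_length_weights={28: 0.5, 29: 0.4}).validate()

    def test_weights_support(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(footprint_length_weights={27: 1.0}).validate()

    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(periodicity=1.2).validate()
        with pytest.raises(ConfigurationError):
            SimulationConfig(feature_plant={"uorf": -0.1}).validate()

    def test_roundtrip_dict(self):
        cfg = SimulationConfig(n_genes=10, seed=5)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestTranscriptome:
    def test_minimal_cds_forced_structure(self):
        cfg = SimulationConfig(n_genes=1, cds_length_range=(9, 9), seed=0)
        (gene,) = simulate_transcriptome(cfg)
        cds = gene.cds_seq
        assert len(cds) == 9
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")

    def test_gene_model_invariants(self, small_config):
        genes = simulate_transcriptome(small_config)
        assert len(genes) == small_config.n_genes
        for g in genes:
            g.validate()  # tiling, ATG start, stop end, no internal stop
            assert g.cds_length % 3 == 0

    def test_determinism_byte_identical(self, small_config, tmp_path):
        from riboprof.io import write_fasta
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(simulate_transcriptome(small_config), a)
        write_fasta(simulate_transcriptome(small_config), b)
        assert a.read_bytes() == b.read_bytes()

    def test_planted_uorf_always_detectable(self):
        cfg = SimulationConfig(n_genes=60, te_effect_genes=0.5, seed=3,
                               feature_plant={"uorf": 1.0})
        genes = simulate_transcriptome(cfg)
        te_up = [g for g in genes if g.condition_class == "te_up"]
        assert te_up
        for g in te_up:
            assert len(brute_uorfs(g.utr5_seq)) >= 1

    def test_background_utrs_have_no_uorfs(self):
        cfg = SimulationConfig(n_genes=50, te_effect_genes=0.0, seed=4)
        genes = simulate_transcriptome(cfg)
        for g in genes:
            assert "ATG" not in g.utr5_seq
            assert find_uorfs(g.utr5_seq) == []

    def test_all_planted_features_redetectable(self, small_config):
        genes = simulate_transcriptome(small_config)
        truth = ground_truth_table(genes).set_index("gene_id")
        by_id = {g.gene_id: g for g in genes}
        planted = truth[truth["condition_class"] == "te_up"]
        assert len(planted) > 0
        for gene_id, row in planted.iterrows():
            u = by_id[gene_id].utr5_seq
            if row["planted_uorf"]:
                assert len(find_uorfs(u)) >= 1
            if row["planted_top"]:
                assert has_top_motif(u)
            if row["planted_pg4"]:
                assert len(find_pg4(u)) >= 1

    def test_ground_truth_consistent_with_models(self, small_config):
        genes = simulate_transcriptome(small_config)
        truth = ground_truth_table(genes)
        assert list(truth["gene_id"]) == [g.gene_id for g in genes]
        assert set(truth["condition_class"]) <= {"te_up", "te_down", "null"}
        for f in PLANTABLE_FEATURES:
            assert f"planted_{f}" in truth.columns


class TestLibraries:
    def test_exact_read_totals(self, small_config):
        genes = simulate_transcriptome(small_config)
        reads = simulate_libraries(genes, small_config)
        per_lib = reads.groupby(["sample", "library"]).size()
        assert (per_lib == small_config.reads_per_library).all()
        n_samples = 2 * small_config.n_replicates
        assert len(per_lib) == 2 * n_samples

    def test_read_bounds_and_lengths(self, small_config):
        genes = simulate_transcriptome(small_config)
        reads = simulate_libraries(genes, small_config)
        tx_len = {g.gene_id: g.length for g in genes}
        ends = reads["start"] + reads["length"]
        assert (reads["start"] >= 0).all()
        assert (ends <= reads["gene_id"].map(tx_len)).all()
        fp = reads[reads["library"] == FOOTPRINT]
        assert fp["length"].between(28, 32).all()
        lo, hi = small_config.mrna_fragment_length_range
        assert reads[reads["library"] == MRNA]["length"].between(lo, hi).all()

    def test_zero_reads_rejected(self, small_config):
        genes = simulate_transcriptome(small_config)
        cfg = SimulationConfig(**{**small_config.to_dict(),
                                  "reads_per_library": 0})
        with pytest.raises(ConfigurationError):
            simulate_libraries(genes, cfg)

    def test_short_gene_skipped_with_warning(self):
        cfg = SimulationConfig(n_genes=5, utr5_length_range=(2, 2),
                               cds_length_range=(30, 30),
                               utr3_length_range=(2, 2),
                               mrna_fragment_length_range=(20, 30),
                               reads_per_library=100, seed=0)
        genes = simulate_transcriptome(cfg)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            with pytest.raises(ConfigurationError):
                # every gene is too short -> no eligible gene at all
                simulate_libraries(genes, cfg)
        assert any("too short" in str(w.message) for w in caught)

    def test_perfect_periodicity_forced(self):
        from riboprof.qc import frame_distribution
        cfg = SimulationConfig(n_genes=20, reads_per_library=2000,
                               periodicity=1.0, seed=5)
        genes = simulate_transcriptome(cfg)
        reads = simulate_libraries(genes, cfg)
        fp = reads[(reads["library"] == FOOTPRINT)
                   & (reads["sample"] == "HFS_rep1")]
        assert frame_distribution(fp, genes) == (1.0, 0.0, 0.0)

    def test_length_weights_chi2_gof(self):
        cfg = SimulationConfig(n_genes=100, reads_per_library=100_000,
                               n_replicates=1, seed=9)
        genes = simulate_transcriptome(cfg)
        reads = simulate_libraries(genes, cfg)
        fp = reads[(reads["library"] == FOOTPRINT)
                   & (reads["sample"] == "HFS_rep1")]
        observed = fp["length"].value_counts().reindex(range(28, 33), fill_value=0)
        expected = np.array([cfg.footprint_length_weights[k]
                             for k in range(28, 33)]) * len(fp)
        _, p = stats.chisquare(observed.to_numpy(), expected)
        assert p > 0.01

    def test_planted_te_effect_recovered_at_depth(self):
        cfg = SimulationConfig(n_genes=50, reads_per_library=100_000,
                               te_effect_genes=0.2, te_log2_effect=1.0,
                               n_replicates=1, abundance_log_sd=0.2, seed=13)
        genes = simulate_transcriptome(cfg)
        reads = simulate_libraries(genes, cfg)
        from riboprof.quant import count_reads, rpkm, translational_efficiency
        cm_fp = count_reads(reads[reads["library"] == FOOTPRINT], genes, "cds_psite")
        cm_m = count_reads(reads[reads["library"] == MRNA], genes,
                           "transcript_overlap")
        te = translational_efficiency(rpkm(cm_fp), rpkm(cm_m),
                                      min_mrna_rpkm=0.0)
        wide = te.table.pivot(index="gene_id", columns="sample", values="log2_te")
        delta = wide["HFS_rep1"] - wide["LFS_rep1"]
        for g in genes:
            if g.condition_class == "te_up":
                assert delta[g.gene_id] == pytest.approx(1.0, abs=0.25)
            elif g.condition_class == "te_down":
                assert delta[g.gene_id] == pytest.approx(-1.0, abs=0.25)

    def test_null_config_has_no_planted_effect(self):
        cfg = SimulationConfig(n_genes=30, te_effect_genes=0.0, seed=2)
        genes = simulate_transcriptome(cfg)
        assert all(g.te_log2_effect == 0.0 for g in genes)
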