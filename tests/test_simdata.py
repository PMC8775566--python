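"""Generator contracts: determinism, marginal distributions, degenerate
configurations, planted structure, and file round-trips."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from linesense import ConfigurationError, SimConfig, io, simdata


class TestGenotypes:
    def test_same_seed_same_table(self, small_config):
        a = simdata.simulate_genotypes(small_config)
        b = simdata.simulate_genotypes(small_config)
        assert np.array_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_minor_class_bounds_and_mean_frequency(self):
        cfg = SimConfig(n_lines=126, n_variants=10_000, seed=1)
        gt = simdata.simulate_genotypes(cfg)
        counts = gt.matrix.sum(axis=1)
        minor = np.minimum(counts, 126 - counts)
        assert minor.max() <= 63
        # allele frequency averages the maf_range midpoint; 3 SE band with
        # binomial sampling on top of the uniform frequency draw
        freqs = counts / 126
        mid = np.mean(cfg.maf_range)
        se = freqs.std(ddof=1) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - mid) < 3 * se

    def test_symmetric_maf_half(self):
        cfg = SimConfig(n_lines=500, n_variants=2000, maf_range=(0.5, 0.5), seed=2)
        gt = simdata.simulate_genotypes(cfg)
        assert abs(gt.matrix.mean() - 0.5) < 0.01

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_lines": 0},
            {"n_variants": 0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"var_error": -1.0},
            {"planted_module_size": 1},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimConfig(**bad).validate()


class TestPhenotypes:
    def test_degenerate_all_zero_variance(self):
        cfg = SimConfig(
            n_lines=5, n_flies_per_cell=3, n_variants=10,
            var_line=0, var_line_by_age=0, var_line_by_treatment=0,
            var_line_by_age_by_treatment=0, var_block=0, var_error=0,
            mass_slope=0, n_causal_trait=0, n_causal_sensitivity=0,
            network_n_genes=10, planted_module_size=2, seed=3,
        )
        geno = simdata.simulate_genotypes(cfg)
        rec, _ = simdata.simulate_phenotypes(cfg, geno)
        expected = (
            cfg.constant
            + cfg.age_effect * (rec["age"] == "old").to_numpy()
            + cfg.treatment_effect * (rec["treatment"] == "treated").to_numpy()
        )
        np.testing.assert_allclose(rec["value"].to_numpy(), expected, atol=1e-12)

    def test_no_gxt_means_uniform_treatment_response(self):
        cfg = SimConfig(
            n_lines=8, n_flies_per_cell=2, n_variants=10,
            var_line_by_treatment=0, var_line_by_age_by_treatment=0,
            n_causal_sensitivity=0, network_n_genes=10, planted_module_size=2, seed=4,
        )
        geno = simdata.simulate_genotypes(cfg)
        _, truth = simdata.simulate_phenotypes(cfg, geno)
        G = truth.true_line_effects
        diff = G[:, :, 1] - G[:, :, 0]  # treated - control per line and age
        assert np.allclose(diff, diff[0], atol=1e-12)

    def test_sensitivity_variants_leave_control_untouched(self):
        cfg = SimConfig(
            n_lines=30, n_flies_per_cell=2, n_variants=20,
            var_line=0, var_line_by_age=0, var_line_by_treatment=0,
            var_line_by_age_by_treatment=0, var_block=0, var_error=0,
            n_causal_trait=0, n_causal_sensitivity=2, causal_effect_size=5.0,
            network_n_genes=10, planted_module_size=2, seed=5,
        )
        g = simdata.simulate_genotypes(cfg)
        _, truth = simdata.simulate_phenotypes(cfg, g)
        G = truth.true_line_effects
        # with no random components, the control stratum carries no genetic
        # signal while the treated one carries exactly the planted dosage
        np.testing.assert_allclose(G[:, :, 0], 0.0, atol=1e-12)
        idx = {v: i for i, v in enumerate(g.variants["variant_id"])}
        dosage = sum(g.matrix[idx[v]] for v in truth.causal_sensitivity_variants)
        np.testing.assert_allclose(G[:, 0, 1], 5.0 * dosage, atol=1e-10)

    def test_line_effect_variance_converges(self):
        cfg = SimConfig(
            n_lines=1000, n_flies_per_cell=1, n_variants=10,
            var_line=0.5, var_line_by_age=0.2, var_line_by_treatment=0.2,
            var_line_by_age_by_treatment=0.1,
            n_causal_trait=0, n_causal_sensitivity=0,
            network_n_genes=10, planted_module_size=2, seed=6,
        )
        geno = simdata.simulate_genotypes(cfg)
        _, truth = simdata.simulate_phenotypes(cfg, geno)
        total = truth.true_line_effects[:, 0, 0].var(ddof=1)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_records_shape_and_balance(self, small_dataset):
        cfg = small_dataset.config
        rec = small_dataset.phenotypes
        assert len(rec) == cfg.n_lines * 2 * 2 * cfg.n_flies_per_cell
        cell_sizes = rec.groupby(["line_id", "age", "treatment"], observed=True).size()
        assert (cell_sizes == cfg.n_flies_per_cell).all()
        # blocks balanced across lines within each age (counts differ by <=1)
        per_block = (
            rec.groupby(["age", "line_id", "block"], observed=True).size().unstack(fill_value=0)
        )
        assert int(per_block.max(axis=None) - per_block.min(axis=None)) <= 1


class TestGenesAndNetwork:
    def test_backbone_with_m1_is_tree(self):
        cfg = SimConfig(
            network_n_genes=80, network_attach_m=1, planted_module_size=5,
            plant_module_edges=False, seed=8,
        )
        _, graph, truth = simdata.simulate_gene_models_and_network(cfg)
        assert graph.number_of_edges() == graph.number_of_nodes() - 1
        assert nx.is_tree(graph)
        # BFS-selected module is connected even without planted edges
        assert nx.is_connected(graph.subgraph(truth.planted_module_genes))

    def test_planted_module_connected(self, small_dataset):
        module = small_dataset.truth.planted_module_genes
        assert len(module) == small_dataset.config.planted_module_size
        assert nx.is_connected(small_dataset.graph.subgraph(module))

    def test_degree_distribution_heavy_tailed(self):
        cfg = SimConfig(network_n_genes=500, network_attach_m=2, seed=7)
        _, graph, _ = simdata.simulate_gene_models_and_network(cfg)
        degrees = np.array([d for _, d in graph.degree()])
        assert degrees.max() > 10 * np.median(degrees)

    def test_gene_intervals_valid_and_disjoint(self, small_dataset):
        genes = small_dataset.genes
        assert (genes["start"] <= genes["end"]).all()
        for _, block in genes.groupby("chrom"):
            b = block.sort_values("start")
            assert (b["start"].to_numpy()[1:] > b["end"].to_numpy()[:-1]).all()

    def test_causal_sensitivity_variants_prefer_module_genes(self, small_dataset):
        pool = set(
            simdata.variants_in_genes(
                small_dataset.genotypes,
                small_dataset.genes,
                small_dataset.truth.planted_module_genes,
            )
        )
        hits = sum(v in pool for v in small_dataset.truth.causal_sensitivity_variants)
        assert hits >= len(small_dataset.truth.causal_sensitivity_variants) / 2


class TestRoundTrips:
    def test_genotype_tsv_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "g.tsv"
        simdata.write_genotypes_tsv(small_dataset.genotypes, p)
        back = io.read_genotypes(p, "tsv")
        assert back.line_ids == small_dataset.genotypes.line_ids
        np.testing.assert_array_equal(back.matrix, small_dataset.genotypes.matrix)
        pd.testing.assert_frame_equal(
            back.variants, small_dataset.genotypes.variants, check_dtype=False
        )

    def test_genotype_vcf_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "g.vcf"
        simdata.write_genotypes_vcf(small_dataset.genotypes, p)
        back = io.read_genotypes(p, "vcf")
        assert back.line_ids == small_dataset.genotypes.line_ids
        np.testing.assert_array_equal(back.matrix, small_dataset.genotypes.matrix)
        assert list(back.variants["vtype"]) == list(small_dataset.genotypes.variants["vtype"])

    def test_bed_round_trip(self, small_dataset, tmp_path):
        p = tmp_path / "genes.bed"
        simdata.write_genes_bed(small_dataset.genes, p)
        back = io.read_gene_models_bed(p)
        pd.testing.assert_frame_equal(
            back[["gene_id", "chrom", "start", "end"]],
            small_dataset.genes[["gene_id", "chrom", "start", "end"]],
            check_dtype=False,
        )

    def test_dataset_deterministic_end_to_end(self, small_config):
        a = simdata.simulate_dataset(small_config)
        b = simdata.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert sorted(a.graph.edges) == sorted(b.graph.edges)
        assert a.truth.causal_sensitivity_variants == b.truth.causal_sensitivity_variants
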