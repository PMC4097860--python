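"""Generator contracts: determinism, forced cases, sampling distributions."""

import numpy as np
import pandas as pd
import pytest

from triplome import simulate as sim
from triplome.config import SimulationConfig
from triplome.methcall import assign_context


class TestGenomeAndGenes:
    def test_seed_determinism_bit_for_bit(self, tiny_config):
        g1, genes1 = sim.simulate_genome_and_genes(tiny_config)
        g2, genes2 = sim.simulate_genome_and_genes(tiny_config)
        assert g1 == g2
        assert [repr(g) for g in genes1] == [repr(g) for g in genes2]

    def test_zero_genes_degenerate_case(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=10_000,
                               n_ancestral_genes=0)
        genome, genes = sim.simulate_genome_and_genes(cfg)
        assert genes == []
        assert len(genome["chr1"]) == 10_000

    def test_forced_gc_composition(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=5_000,
                               n_ancestral_genes=0, gc_fraction=1.0)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        assert set(genome["chr1"]) <= {"G", "C"}

    def test_chromosome_too_short_is_an_error(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=6_000,
                               n_ancestral_genes=30)
        with pytest.raises(ValueError, match="too short"):
            sim.simulate_genome_and_genes(cfg)

    def test_genes_do_not_overlap_and_parts_tile_gene(self, tiny_config):
        _, genes = sim.simulate_genome_and_genes(tiny_config)
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for g in genes:
            ivs = sorted(
                iv for part in ("five_prime_UTR", "exon", "intron", "three_prime_UTR")
                for iv in g.parts[part]
            )
            assert ivs[0][0] == g.start and ivs[-1][1] == g.end
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                assert c == b + 1


class TestFractionation:
    def test_full_and_zero_retention(self):
        cfg = SimulationConfig(seed=1, n_ancestral_genes=200,
                               retention_probs=(1.0, 1.0, 1.0))
        truth = sim.simulate_fractionation(cfg)
        assert truth.syntelog[["LF", "MF1", "MF2"]].notna().all().all()
        cfg2 = SimulationConfig(seed=1, n_ancestral_genes=200,
                                retention_probs=(0.0, 0.0, 0.0))
        truth2 = sim.simulate_fractionation(cfg2)
        assert truth2.syntelog[["LF", "MF1", "MF2"]].isna().all().all()

    def test_retained_fractions_within_three_binomial_se(self):
        cfg = SimulationConfig(seed=7, n_ancestral_genes=10_000,
                               retention_probs=(0.5, 0.35, 0.3))
        truth = sim.simulate_fractionation(cfg)
        for g, p in zip(("LF", "MF1", "MF2"), (0.5, 0.35, 0.3)):
            frac = truth.syntelog[g].notna().mean()
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(frac - p) < 3 * se

    def test_anchor_hits_pass_filter_thresholds(self):
        cfg = SimulationConfig(seed=7, n_ancestral_genes=500)
        truth = sim.simulate_fractionation(cfg)
        anchors = {(a.query_gene, a.target_gene)
                   for alist in truth.anchors.values() for a in alist}
        true_rows = truth.hits.set_index(["qseqid", "sseqid"]).index.isin(anchors)
        assert (truth.hits.loc[true_rows, "evalue"] <= 1e-20).all()
        assert len(truth.hits) > len(anchors)  # decoys present


class TestMethylome:
    def test_no_error_no_methylation_means_zero_counts(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=5_000,
                               n_ancestral_genes=0, nonconversion_e=0.0,
                               true_meth_levels={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
                               lambda_length_bp=1_000)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        sites, lam = sim.simulate_methylome_counts(cfg, genome)
        assert (sites["C_count"] == 0).all()
        assert (lam["C_count"] == 0).all()

    def test_full_methylation_means_all_reads_methylated(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=5_000,
                               n_ancestral_genes=0,
                               true_meth_levels={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
                               lambda_length_bp=1_000)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        sites, _ = sim.simulate_methylome_counts(cfg, genome)
        assert (sites["C_count"] == sites["eff_CT_count"]).all()

    def test_control_error_rate_within_three_se(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=1, chrom_length_bp=1_000,
                               n_ancestral_genes=0, nonconversion_e=0.005)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        _, lam = sim.simulate_methylome_counts(cfg, genome)
        n = lam["eff_CT_count"].sum()
        e_hat = lam["C_count"].sum() / n
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(e_hat - 0.005) < 3 * se

    def test_contexts_match_exhaustive_scan_of_1kb(self):
        cfg = SimulationConfig(seed=9, n_chromosomes=1, chrom_length_bp=1_000,
                               n_ancestral_genes=0, lambda_length_bp=1_000)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        sites, _ = sim.simulate_methylome_counts(cfg, genome)
        seq = genome["chr1"]
        for _, row in sites.iterrows():
            assert row["context"] == assign_context(seq, row["pos"], row["strand"])
        # every C/G position is present exactly once per strand
        n_c = seq.count("C")
        n_g = seq.count("G")
        assert (sites["strand"] == "+").sum() == n_c
        assert (sites["strand"] == "-").sum() == n_g

    def test_zero_coverage_sites_are_emitted(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1, chrom_length_bp=20_000,
                               n_ancestral_genes=0, depth_lambda=1.0,
                               lambda_length_bp=1_000)
        genome, _ = sim.simulate_genome_and_genes(cfg)
        sites, _ = sim.simulate_methylome_counts(cfg, genome)
        assert (sites["eff_CT_count"] == 0).any()
        assert sites.loc[sites["eff_CT_count"] == 0, "ratio"].isna().all()


class TestExpression:
    @staticmethod
    def _triplets(n):
        return pd.DataFrame({
            "triplet_id": [f"t{i}" for i in range(n)],
            "lf_gene": [f"lf{i}" for i in range(n)],
            "mf1_gene": [f"m1{i}" for i in range(n)],
            "mf2_gene": [f"m2{i}" for i in range(n)],
        })

    def test_noiseless_closed_form(self):
        cfg = SimulationConfig(seed=1)
        cfg.expr_model.mu = np.log(2.0)
        for s in ("sigma_G", "sigma_T", "sigma_GT", "sigma_eps"):
            setattr(cfg.expr_model, s, 0.0)
        fpkm = sim.simulate_expression_triplets(cfg, self._triplets(5))
        for mat in fpkm.values():
            assert np.allclose(mat, 1.0)

    def test_large_lf_shift_forces_lf_dominance(self):
        cfg = SimulationConfig(seed=1)
        cfg.expr_model.lf_shift_delta = 8.0
        fpkm = sim.simulate_expression_triplets(cfg, self._triplets(50))
        for mat in fpkm.values():
            means = np.log1p(mat).mean(axis=1)
            assert means[0] == max(means)

    def test_fpkm_nonnegative(self):
        cfg = SimulationConfig(seed=2)
        cfg.expr_model.mu = -1.0  # pushes many values to the clip boundary
        fpkm = sim.simulate_expression_triplets(cfg, self._triplets(50))
        assert all((m >= 0).all() for m in fpkm.values())


class TestFdrProgeny:
    def test_centromere_marker_fully_heterozygous(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=100_000,
                               n_ancestral_genes=0)
        cfg.meiosis.centromere_pos_bp = 1  # exactly at the first marker
        cfg.meiosis.n_progeny = 60
        geno = sim.simulate_fdr_progeny(cfg)
        first = geno.iloc[0, 3:]
        assert (first == "het").all()

    def test_zero_map_length_means_all_heterozygous(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=100_000,
                               n_ancestral_genes=0)
        cfg.meiosis.map_length_morgans = 0.0
        geno = sim.simulate_fdr_progeny(cfg)
        assert (geno.iloc[:, 3:] == "het").all().all()

    def test_het_frequency_matches_four_strand_closed_form(self):
        """Mather's no-interference result: h(x) = (2 + exp(-3x)) / 3."""
        cfg = SimulationConfig(seed=8, n_chromosomes=1, chrom_length_bp=100_000,
                               n_ancestral_genes=0)
        cfg.meiosis.centromere_pos_bp = 1
        cfg.meiosis.map_length_morgans = 1.5
        cfg.meiosis.n_markers = 6
        cfg.meiosis.n_progeny = 4000
        geno = sim.simulate_fdr_progeny(cfg)
        states = geno.iloc[:, 3:]
        het = (states == "het").sum(axis=1) / states.notna().sum(axis=1)
        L = cfg.meiosis.map_length_morgans
        x = L * (geno["pos"].to_numpy() - 1) / (cfg.chrom_length_bp - 1)
        expected = sim.expected_fdr_het_frequency(x)
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert (np.abs(het.to_numpy() - expected) < 3 * np.maximum(se, 1e-9)).all()

    def test_asymptote_is_two_thirds_not_one_half(self):
        assert sim.expected_fdr_het_frequency(50.0) == pytest.approx(2 / 3)
        x = np.linspace(0, 5, 50)
        h = sim.expected_fdr_het_frequency(x)
        assert h[0] == pytest.approx(1.0)
        assert (np.diff(h) <= 0).all()

    def test_missing_rate_and_centromere_bounds(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length_bp=100_000,
                               n_ancestral_genes=0)
        cfg.meiosis.missing_rate = 0.3
        geno = sim.simulate_fdr_progeny(cfg)
        frac_missing = geno.iloc[:, 3:].isna().mean().mean()
        assert 0.2 < frac_missing < 0.4
        cfg.meiosis.centromere_pos_bp = 10**9
        with pytest.raises(ValueError):
            cfg.validate()
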