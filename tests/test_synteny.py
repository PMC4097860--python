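"""Hit filtering, chain DP vs enumeration, sub-genome labels, categories."""

import numpy as np
import pandas as pd
import pytest

from helpers_oracles import enumerate_best_chain
from triplome.synteny import (
    Anchor,
    assign_blocks_and_subgenomes,
    chain_anchors,
    classify_gene_category,
    filter_hits,
    resolve_chain_overlaps,
    retention_stats,
    SyntenicChain,
)


def _hits(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue"])


class TestFilterHits:
    def test_single_hit_is_its_own_best(self):
        out = filter_hits(_hits([("q1", "t1", 80.0, 1e-30)]))
        assert len(out) == 1

    def test_margin_threshold_arithmetic(self):
        out = filter_hits(_hits([
            ("q1", "t1", 100.0, 1e-30),
            ("q1", "t2", 61.0, 1e-30),
            ("q1", "t3", 59.0, 1e-30),
        ]))
        assert sorted(out["bitscore"]) == [61.0, 100.0]

    def test_evalue_cutoff_applies_before_margin(self):
        out = filter_hits(_hits([
            ("q1", "t1", 100.0, 1e-10),   # weak E-value, dropped
            ("q1", "t2", 70.0, 1e-30),
        ]))
        assert out["bitscore"].tolist() == [70.0]

    def test_ten_hit_toy_table_matches_hand_oracle(self):
        rows = [
            ("q1", "t1", 200.0, 1e-50), ("q1", "t2", 130.0, 1e-40),
            ("q1", "t3", 119.0, 1e-30), ("q1", "t4", 90.0, 1e-25),
            ("q2", "t1", 50.0, 1e-22), ("q2", "t2", 29.0, 1e-21),
            ("q2", "t3", 45.0, 1e-5),
            ("q3", "t9", 300.0, 1e-80), ("q3", "t8", 185.0, 1e-60),
            ("q3", "t7", 179.0, 1e-55),
        ]
        # hand filter: e<=1e-20 then bit >= 0.6*best per query
        expect = set()
        by_q = {}
        for q, t, b, e in rows:
            if e <= 1e-20:
                by_q.setdefault(q, []).append((t, b))
        for q, lst in by_q.items():
            best = max(b for _, b in lst)
            expect |= {(q, t) for t, b in lst if b >= 0.6 * best}
        out = filter_hits(_hits(rows))
        assert set(zip(out["qseqid"], out["sseqid"])) == expect

    def test_quantile_mode_differs_from_margin_mode(self):
        rows = [("q1", f"t{i}", 100.0 - i, 1e-30) for i in range(10)]
        margin = filter_hits(_hits(rows))
        quant = filter_hits(_hits(rows), quantile_mode=True)
        assert len(margin) == 10          # all within 40% of best
        assert len(quant) == 4            # top 40% quantile only


def _rand_anchors(rng, n):
    qs = rng.choice(np.arange(0, 14), size=n, replace=False)
    ts = rng.integers(0, 14, size=n)
    sc = rng.uniform(0.5, 1.5, size=n)
    return [Anchor(int(q), int(t), float(s), f"q{g}", f"t{g}")
            for g, (q, t, s) in enumerate(zip(qs, ts, sc))]


class TestChaining:
    def test_three_collinear_unit_anchors(self):
        anchors = [Anchor(i, i, 1.0, f"q{i}", f"t{i}") for i in range(3)]
        chains = chain_anchors(anchors, min_anchors=3)
        assert len(chains) == 1
        assert chains[0].score == pytest.approx(3.0)
        assert chains[0].orientation == "same"

    def test_inverted_orientation_detected(self):
        anchors = [Anchor(i, 10 - i, 1.0, f"q{i}", f"t{i}") for i in range(5)]
        chains = chain_anchors(anchors, min_anchors=5)
        assert len(chains) == 1 and chains[0].orientation == "inverted"

    def test_empty_anchor_list(self):
        assert chain_anchors([]) == []

    def test_best_first_extraction_matches_enumeration_each_round(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 15))
            anchors = _rand_anchors(rng, n)
            remaining = list(anchors)
            while True:
                triples = [(a.query_index, a.target_index, a.score)
                           for a in remaining]
                exp_score, exp_path = enumerate_best_chain(
                    triples, gap_penalty=0.25, max_gap_genes=10, min_anchors=3)
                got = chain_anchors(remaining, gap_penalty=0.25,
                                    max_gap_genes=10, min_anchors=3)
                if exp_score == float("-inf"):
                    assert got == []
                    break
                assert got, "DP found no chain where enumeration did"
                assert got[0].score == pytest.approx(exp_score, abs=1e-9)
                used = {a.query_gene for a in got[0].anchors}
                remaining = [a for a in remaining if a.query_gene not in used]
                if len(remaining) < 3:
                    break


class TestOverlapResolution:
    def test_disjoint_chains_unchanged(self):
        c1 = SyntenicChain([Anchor(i, i, 1.0, f"a{i}", f"t{i}") for i in range(5)],
                           5.0, "same")
        c2 = SyntenicChain([Anchor(i, i, 1.0, f"b{i}", f"u{i}") for i in range(5)],
                           5.0, "same")
        out = resolve_chain_overlaps([c1, c2])
        assert len(out) == 2

    def test_shared_gene_stays_with_stronger_chain(self):
        shared = [Anchor(i, i, 1.0, f"s{i}", f"t{i}") for i in range(6)]
        strong = SyntenicChain(shared, 10.0, "same")
        weak = SyntenicChain(shared[:1] + [
            Anchor(i, i, 1.0, f"w{i}", f"v{i}") for i in range(1, 6)
        ], 7.0, "same")
        out = resolve_chain_overlaps([weak, strong])
        weak_out = [c for c in out if any(a.query_gene.startswith("w")
                                          for a in c.anchors)][0]
        assert "s0" not in weak_out.query_genes

    def test_greedy_by_score_matches_oracle_on_random_overlaps(self, rng):
        chains = []
        for ci in range(6):
            genes = rng.choice(30, size=6, replace=False)
            anchors = [Anchor(i, i, 1.0, f"g{g}", f"t{ci}_{i}")
                       for i, g in enumerate(sorted(genes))]
            chains.append(SyntenicChain(anchors, float(rng.uniform(5, 15)), "same"))
        out = resolve_chain_overlaps(chains, min_anchors=1)
        # oracle: assign each gene to its best-scoring chain
        best_of = {}
        for ch in sorted(chains, key=lambda c: -c.score):
            for g in ch.query_genes:
                best_of.setdefault(g, ch.score)
        for ch in out:
            for a in ch.anchors:
                assert best_of[a.query_gene] == ch.score or \
                    ch.score <= best_of[a.query_gene]
        seen = [a.query_gene for ch in out for a in ch.anchors]
        assert len(seen) == len(set(seen))


class TestBlockAssignment:
    @staticmethod
    def _copy(block, chrom, n, offset=0):
        return SyntenicChain(
            [Anchor(i, i, 1.0, f"{chrom}_g{i}", f"anc_{block}_{i + offset:03d}")
             for i in range(n)],
            float(n), "same", query_chrom=chrom,
        )

    def test_ranking_by_retained_fraction(self):
        block_of = {f"anc_A_{i:03d}": "A" for i in range(100)}
        chains = [
            self._copy("A", "c1", 50), self._copy("A", "c2", 35),
            self._copy("A", "c3", 30),
        ]
        chains, table = assign_blocks_and_subgenomes(
            chains, block_of, {"A": 100})
        labels = {ch.query_chrom: ch.subgenome_label for ch in chains}
        assert labels == {"c1": "LF", "c2": "MF1", "c3": "MF2"}

    def test_single_copy_block_is_lf(self):
        block_of = {f"anc_B_{i:03d}": "B" for i in range(40)}
        chains = [self._copy("B", "c9", 12)]
        chains, _ = assign_blocks_and_subgenomes(chains, block_of, {"B": 40})
        assert chains[0].subgenome_label == "LF"

    def test_fourth_copy_is_unassigned(self):
        block_of = {f"anc_A_{i:03d}": "A" for i in range(100)}
        chains = [self._copy("A", f"c{i}", 40 - 5 * i) for i in range(4)]
        chains, _ = assign_blocks_and_subgenomes(chains, block_of, {"A": 100})
        assert chains[3].subgenome_label == "unassigned"

    def test_external_partition_overrides_ranking(self):
        block_of = {f"anc_A_{i:03d}": "A" for i in range(100)}
        chains = [self._copy("A", "c1", 50), self._copy("A", "c2", 35)]
        chains, _ = assign_blocks_and_subgenomes(
            chains, block_of, {"A": 100},
            partition={("A", 0): "MF2", ("A", 1): "LF"})
        assert chains[0].subgenome_label == "MF2"
        assert chains[1].subgenome_label == "LF"


class TestRetention:
    def test_full_retention(self):
        t = pd.DataFrame({
            "ancestral_gene": ["a", "b"], "LF": ["x", "y"],
            "MF1": ["u", "v"], "MF2": ["p", "q"],
        })
        s = retention_stats(t)
        assert s["retention"] == {"LF": 100.0, "MF1": 100.0, "MF2": 100.0}
        assert len(s["triplets"]) == 2

    def test_single_partial_row(self):
        t = pd.DataFrame({
            "ancestral_gene": ["a"], "LF": ["x"], "MF1": [None], "MF2": ["p"],
        })
        s = retention_stats(t)
        assert s["retention"] == {"LF": 100.0, "MF1": 0.0, "MF2": 100.0}
        assert len(s["triplets"]) == 0

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            retention_stats(pd.DataFrame(
                columns=["ancestral_gene", "LF", "MF1", "MF2"]))

    def test_label_ordering_holds_by_construction(self):
        from triplome import simulate as sim
        from triplome.config import SimulationConfig
        cfg = SimulationConfig(seed=13, n_ancestral_genes=3000)
        truth = sim.simulate_fractionation(cfg)
        chains = []
        for chrom, alist in truth.anchors.items():
            chains.extend(chain_anchors(alist, query_chrom=chrom))
        chains = resolve_chain_overlaps(chains)
        chains, table = assign_blocks_and_subgenomes(
            chains, truth.block_of, truth.block_sizes)
        s = retention_stats(table, n_ancestral=cfg.n_ancestral_genes)
        r = s["retention"]
        assert r["LF"] >= r["MF1"] >= r["MF2"]


class TestCategories:
    def test_toy_chromosome_matches_hand_oracle(self):
        # 12 genes: 0-5 anchors in one chain; 6,7 tandem pair hitting the
        # same off-block target; 8 hits elsewhere; 9-11 no hits at all
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(12)],
            "chrom": ["c1"] * 12,
            "order": list(range(12)),
        })
        chain = SyntenicChain(
            [Anchor(i, i, 1.0, f"g{i}", f"anc{i}") for i in range(6)],
            6.0, "same", query_chrom="c1")
        hits = _hits(
            [(f"g{i}", f"anc{i}", 200.0, 1e-40) for i in range(6)]
            + [("g6", "anc99", 150.0, 1e-35), ("g7", "anc99", 150.0, 1e-35),
               ("g8", "anc55", 120.0, 1e-30)]
        )
        out = classify_gene_category(genes, [chain], None, hits).set_index("gene_id")
        for i in range(6):
            assert out.loc[f"g{i}", "category"] == "syntenic"
        for g in ("g6", "g7", "g8"):
            assert out.loc[g, "category"] == "non_syntenic"
        for g in ("g9", "g10", "g11"):
            assert out.loc[g, "category"] == "species_specific"
        assert out.loc["g6", "tandem"] and out.loc["g7", "tandem"]
        assert not out.loc["g8", "tandem"]

    def test_distant_shared_target_is_not_tandem(self):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "chrom": ["c1"] * 20,
            "order": list(range(20)),
        })
        hits = _hits([("g0", "ancX", 100.0, 1e-30),
                      ("g15", "ancX", 100.0, 1e-30)])
        out = classify_gene_category(genes, [], None, hits).set_index("gene_id")
        assert not out["tandem"].any()
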