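import math

import numpy as np
import pandas as pd
import pytest

from orthoflora.clade import classify_target_gene, parse_newick
from orthoflora.distribution import window_scan
from orthoflora.expression import call_active, hierarchical_cluster, zscore_rows
from orthoflora.paralogue import compute_ratios, distribution_summary
from orthoflora.simulate import (
    SimulationConfig,
    generate_expression,
    generate_gene_tree,
    generate_genome_and_variants,
    generate_og_universe,
    og_gene_catalogue,
    stream_rng,
)
from orthoflora.variants import categorize_snp, sv_overlap

from tests.oracles import ari_formula


class TestOgUniverse:
    def test_zero_spread_pins_generating_ratio(self):
        # mean 1.0 is exactly representable: target = 2 * reference
        cfg = SimulationConfig(seed=1, n_ogs=50, log2_ratio_mean=1.0, log2_ratio_sd=0.0)
        counts, truth = generate_og_universe(cfg)
        assert (truth["true_log2"] == 1.0).all()
        assert (truth["true_class"] == "typical").all()
        assert (counts["n_target"] == 2 * counts["n_reference"]).all()

    def test_parameter_recovery_within_three_se(self):
        cfg = SimulationConfig(seed=42, n_ogs=10_000)
        counts, _ = generate_og_universe(cfg)
        ratios, excluded = compute_ratios(counts)
        assert excluded.empty
        s = distribution_summary(ratios)
        se = cfg.log2_ratio_sd / math.sqrt(cfg.n_ogs)
        assert abs(s.mean_log2 - cfg.log2_ratio_mean) < 3 * se
        assert abs(s.sd_log2 - cfg.log2_ratio_sd) < 0.05

    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = SimulationConfig(seed=7, n_ogs=100)
        a, ta = generate_og_universe(cfg)
        b, tb = generate_og_universe(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimulationConfig(log2_ratio_sd=-0.1)

    def test_catalogue_counts_match_table(self):
        cfg = SimulationConfig(seed=3, n_ogs=20)
        counts, _ = generate_og_universe(cfg)
        catalogue = og_gene_catalogue(counts)
        per_og = catalogue.groupby(["og_id", "species"]).size().unstack(fill_value=0)
        merged = counts.set_index("og_id")
        assert (per_og["reference"] == merged["n_reference"]).all()
        assert (per_og["target"] == merged["n_target"]).all()
        assert catalogue["gene_id"].is_unique


class TestGeneTrees:
    def test_single_pair_is_cherry_with_sole_anchor(self):
        cfg = SimulationConfig(seed=2)
        newick, truth = generate_gene_tree(["AT1G00001"], ["Glyma01g00001"], cfg)
        assert truth == {"Glyma01g00001": ["AT1G00001"]}
        tree = parse_newick(newick)
        assert sorted(tree.leaf_names) == ["AT1G00001", "Glyma01g00001"]

    def test_same_seed_reproduces_identical_newick(self):
        cfg = SimulationConfig(seed=13, branch_noise_sd=0.1)
        refs = ["AT1G1", "AT1G2"]
        tgts = ["Glyma01g1", "Glyma01g2", "Glyma01g3"]
        a, _ = generate_gene_tree(refs, tgts, cfg, stream_rng(13, "trees"))
        b, _ = generate_gene_tree(refs, tgts, cfg, stream_rng(13, "trees"))
        assert a == b

    def test_zero_noise_classifier_recovers_all_anchors(self):
        """With noiseless branch lengths the clade rule matches the
        planted duplication history on every target leaf."""
        cfg = SimulationConfig(seed=4, branch_noise_sd=0.0)
        trng = stream_rng(4, "trees")
        for i in range(40):
            n_ref, n_tgt = int(trng.integers(1, 4)), int(trng.integers(1, 5))
            refs = [f"AT1G{i:03d}{j}" for j in range(n_ref)]
            tgts = [f"Glyma01g{i:03d}{j}" for j in range(n_tgt)]
            newick, truth = generate_gene_tree(refs, tgts, cfg, trng)
            tree = parse_newick(newick)
            flowering = set(truth[tgts[0]])
            for t in tgts:
                anchors = set(truth[t])
                a = classify_target_gene(tree, t, flowering)
                if anchors <= flowering:
                    assert a.status == "flowering_orthologue"
                    assert a.anchor_reference_genes <= flowering
                elif not anchors & flowering:
                    assert a.status == "other_orthologue"


class TestExpressionGenerator:
    def test_zero_dispersion_returns_templates_exactly(self):
        cfg = SimulationConfig(seed=5, nb_dispersion=0.0, zero_gene_fraction=0.0)
        genes = [f"g{i}" for i in range(12)]
        matrix, labels = generate_expression(genes, cfg)
        values = matrix.values.to_numpy()
        # all genes of one planted cluster share one exact integer profile
        for lab in set(labels) - {-1}:
            rows = values[(labels == lab).to_numpy()]
            assert (rows == rows[0]).all()

    def test_planted_clusters_recovered_by_clustering(self):
        cfg = SimulationConfig(
            seed=6, nb_dispersion=0.05, zero_gene_fraction=0.0,
            n_expression_clusters=3,
        )
        genes = [f"g{i}" for i in range(60)]
        matrix, labels = generate_expression(genes, cfg)
        dendro = hierarchical_cluster(zscore_rows(matrix))
        flat = dendro.cut_k(3)
        got = [flat[g] for g in genes]
        assert ari_formula(got, labels.tolist()) >= 0.9

    def test_all_zero_genes_inactive_under_both_rules(self):
        cfg = SimulationConfig(seed=7, zero_gene_fraction=0.3)
        genes = [f"g{i}" for i in range(40)]
        matrix, labels = generate_expression(genes, cfg)
        zero_genes = set(labels[labels == -1].index)
        assert zero_genes
        raw_calls = {c.gene_id: c for c in call_active(matrix)}
        norm = matrix.values.astype(float)
        from orthoflora.expression import ExpressionMatrix

        norm_calls = {
            c.gene_id: c
            for c in call_active(
                ExpressionMatrix(values=norm, rule_tag="normalized")
            )
        }
        for g in zero_genes:
            assert not raw_calls[g].active_any
            assert not norm_calls[g].active_any


class TestGenomeAndVariants:
    def test_planted_snp_categories_reproduced_exactly(self, small_sim_config):
        genes = [f"Glyma01g{i:04d}" for i in range(320)]
        out = generate_genome_and_variants(genes, small_sim_config)
        models = {m.gene_id: m for m in out["gene_models"]}
        snps = {v.id: v for v in out["snps"]}
        checked = 0
        for row in out["snp_truth"].itertuples():
            if row.true_category == "intergenic":
                continue
            got = categorize_snp(snps[row.snp_id], models[row.gene_id])
            expected = (
                row.true_category if row.true_category != "intergenic" else "outside"
            )
            assert got == expected
            checked += 1
        assert checked > 30

    def test_intergenic_snps_outside_every_gene(self, small_sim_config):
        genes = [f"Glyma01g{i:04d}" for i in range(320)]
        out = generate_genome_and_variants(genes, small_sim_config)
        snps = {v.id: v for v in out["snps"]}
        inter = out["snp_truth"].query("true_category == 'intergenic'")
        import warnings

        for row in inter.itertuples():
            snp = snps[row.snp_id]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for m in out["gene_models"]:
                    assert categorize_snp(snp, m) == "outside"

    def test_planted_cluster_found_by_window_scan(self, small_sim_config):
        genes = [f"Glyma01g{i:04d}" for i in range(320)]
        out = generate_genome_and_variants(genes, small_sim_config)
        hits = window_scan(
            out["gene_records"], out["flagged"],
            window_size=1_400_000, step=100_000,
        )
        top = hits.iloc[0]
        lo, hi = out["cluster_interval"]
        assert top["chrom"] == out["cluster_chrom"]
        assert top["window_start"] <= hi and lo <= top["window_end"]
        assert top["n_flagged_in_window"] >= 0.9 * small_sim_config.cluster_size

    def test_sv_truth_matches_overlap_call(self, small_sim_config):
        genes = [f"Glyma01g{i:04d}" for i in range(320)]
        out = generate_genome_and_variants(genes, small_sim_config)
        flags = sv_overlap(out["svs"], out["gene_models"], include_promoter=False)
        assert flags == out["sv_truth"]

    def test_zero_variant_rates_give_empty_tables(self):
        cfg = SimulationConfig(
            seed=8, n_background_genes=150,
            n_snps_cds=0, n_snps_genic_noncoding=0, n_snps_promoter=0,
            n_snps_intergenic=0, n_svs=0,
        )
        genes = [f"Glyma01g{i:04d}" for i in range(250)]
        out = generate_genome_and_variants(genes, cfg)
        assert out["snps"] == [] and out["svs"] == []

    def test_gene_placement_no_overlap(self, small_sim_config):
        genes = [f"Glyma01g{i:04d}" for i in range(320)]
        out = generate_genome_and_variants(genes, small_sim_config)
        by_chrom: dict[str, list] = {}
        for g in out["gene_records"]:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
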