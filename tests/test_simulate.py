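"""Synthetic-study generator: genomes, truths, counts, reads, expression."""

import numpy as np
import pandas as pd
import pytest

from damidscope import (
    SimConfig,
    digest_genome,
    plant_truth,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_reads,
)
from damidscope import io as dio
from damidscope.digest import SiteIndex
from damidscope.genesets import enriched_genes, expressed_genes


class TestGenome:
    def test_gatc_density_near_target(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=50_000, n_genes=0)
        genome, genes, features, _ = simulate_genome(cfg)
        n = len(digest_genome(genome))
        sd = np.sqrt(50_000 * (1 / 256) * (255 / 256))
        assert abs(n - 50_000 / 256) <= 4 * sd

    def test_custom_gatc_rate_honoured(self):
        cfg = SimConfig(seed=2, n_chroms=1, chrom_length=50_000,
                        gatc_rate=1 / 100, n_genes=0)
        genome, *_ = simulate_genome(cfg)
        n = len(digest_genome(genome))
        assert abs(n - 500) <= 4 * np.sqrt(500)

    def test_no_genes_empty_annotation(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=20_000, n_genes=0)
        genome, genes, features, _ = simulate_genome(cfg)
        truth = plant_truth(genome, genes, cfg)
        assert len(genes) == 0 and len(features) == 0
        assert truth.expressed_genes == set()

    def test_too_many_genes_raises_sizing_error(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=12_000, n_genes=10)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg)

    def test_genes_do_not_overlap_and_have_structure(self, small_study):
        genes = small_study["genes"].sort_values("start")
        assert (genes["start"].to_numpy()[1:]
                >= genes["end"].to_numpy()[:-1]).all()
        feats = small_study["features"]
        for gid, sub in feats.groupby("gene_id"):
            kinds = set(sub["feature"])
            assert {"exon", "utr5", "utr3"} <= kinds
            span = genes.set_index("gene_id").loc[gid]
            assert sub["start"].min() == span["start"]
            assert sub["end"].max() == span["end"]

    def test_enhancer_classes_disjoint(self, small_study):
        enh = small_study["enhancers"]
        assert set(enh) == {"developmental", "housekeeping"}
        spans = pd.concat(enh.values())
        spans = spans.sort_values(["chrom", "start"])
        same = spans.groupby("chrom")
        for _, sub in same:
            assert (sub["start"].to_numpy()[1:]
                    >= sub["end"].to_numpy()[:-1]).all()

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=9, n_chroms=2, chrom_length=30_000, n_genes=4)
        paths = []
        for run in ("a", "b"):
            genome, genes, features, _ = simulate_genome(cfg)
            fa = tmp_path / f"{run}.fa"
            gtf = tmp_path / f"{run}.gtf"
            dio.write_fasta(genome, str(fa))
            dio.write_gtf(genes, features, str(gtf))
            paths.append((fa.read_bytes(), gtf.read_bytes()))
        assert paths[0] == paths[1]


class TestTruth:
    def test_blocks_inside_chromosomes_and_cover_two_sites(self, default_study):
        truth = default_study["truth"]
        index = default_study["index"]
        sizes = {c: len(s) for c, s in default_study["genome"].items()}
        for factor, blocks in truth.bound_blocks.items():
            for b in blocks.itertuples():
                assert 0 <= b.start < b.end <= sizes[b.chrom]
                assert len(index.contained(b.chrom, b.start, b.end)) >= 2

    def test_truth_genes_exist_in_annotation(self, default_study):
        gene_ids = set(default_study["genes"]["gene_id"])
        truth = default_study["truth"]
        assert truth.expressed_genes <= gene_ids
        for s in truth.enriched_genes.values():
            assert s <= gene_ids
        for d in truth.de_truth.values():
            assert set(d) <= gene_ids


class TestCounts:
    def test_nb_marginals_match_moments(self):
        cfg = SimConfig(seed=4, planted_log2fc=0.0)
        genome, genes, *_ = simulate_genome(cfg)
        truth = plant_truth(genome, genes, cfg)
        index = SiteIndex(digest_genome(genome))
        table = simulate_counts(index, truth, cfg, "kis")
        col = table.matrix[:, 0].astype(float)
        lib = table.samples["libsize"].iloc[0]
        mu = cfg.baseline_mean * lib
        n = len(col)
        assert abs(col.mean() - mu) <= 3 * np.sqrt(
            (mu + cfg.dispersion * mu ** 2) / n)
        expected_var = mu + cfg.dispersion * mu ** 2
        # variance of the sample variance ~ 2 var^2 / n for near-normal
        assert abs(col.var() - expected_var) <= 4 * expected_var * np.sqrt(2 / n)

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = SimConfig(seed=4, dispersion=0.0, planted_log2fc=0.0,
                        libsize_spread=(1.0, 1.0))
        genome, genes, *_ = simulate_genome(cfg)
        truth = plant_truth(genome, genes, cfg)
        index = SiteIndex(digest_genome(genome))
        table = simulate_counts(index, truth, cfg, "kis")
        col = table.matrix[:, 0].astype(float)
        assert len(col) >= 1_000
        assert abs(col.var() / col.mean() - 1.0) < 0.1

    def test_block_mean_scales_with_planted_fold_change(self, default_study):
        cfg = default_study["config"]
        truth, index = default_study["truth"], default_study["index"]
        table = simulate_counts(index, truth, cfg, "kis")
        mask = truth.bound_site_mask(index, "kis")
        fusion = table.role_columns("fusion")
        libs = table.samples["libsize"].to_numpy()[fusion]
        for j, lib in zip(fusion, libs):
            inside = table.matrix[mask, j].mean()
            assert abs(inside - 200 * lib) < 0.1 * 200 * lib

    def test_unknown_factor_rejected(self, default_study):
        with pytest.raises(KeyError):
            simulate_counts(default_study["index"], default_study["truth"],
                            default_study["config"], "nonesuch")


class TestReads:
    def test_zero_depth_gives_empty_bed(self, small_study):
        reads = simulate_reads(small_study["index"], small_study["truth"],
                               small_study["config"], "kis",
                               depth_scale=0.0)
        assert len(reads) == 0

    def test_deterministic_under_seed(self, small_study):
        a = simulate_reads(small_study["index"], small_study["truth"],
                           small_study["config"], "kis")
        b = simulate_reads(small_study["index"], small_study["truth"],
                           small_study["config"], "kis")
        pd.testing.assert_frame_equal(a, b)

    def test_reads_cover_their_source_motif(self, small_study):
        index = small_study["index"]
        reads = simulate_reads(index, small_study["truth"],
                               small_study["config"], "kis")
        sites = index.sites
        starts = {c: s.to_numpy() for c, s in
                  sites.groupby("chrom")["start"]}
        for r in reads.head(200).itertuples():
            s = starts[r.chrom]
            covered = s[(s < r.end) & (s + 4 > r.start)]
            assert len(covered) >= 1


class TestExpression:
    @pytest.fixture(scope="class")
    def tables(self, default_study):
        rpkm, de = simulate_expression(default_study["genes"],
                                       default_study["truth"],
                                       default_study["config"])
        return rpkm, de

    def test_planted_lists_recovered_exactly(self, default_study, tables):
        rpkm, _ = tables
        truth = default_study["truth"]
        assert expressed_genes(rpkm, "ISC") == truth.expressed_genes
        for ct in ("ISC", "EE", "EC"):
            assert enriched_genes(rpkm, ct) == truth.enriched_genes[ct]

    def test_de_overlap_and_sign_structure(self, default_study, tables):
        _, de = tables
        cfg = default_study["config"]
        truth = default_study["truth"]
        kd_a, kd_b = cfg.knockdowns
        da = set(de[kd_a].index[de[kd_a]["padj"] < 0.01])
        db = set(de[kd_b].index[de[kd_b]["padj"] < 0.01])
        assert da == set(truth.de_truth[kd_a])
        n_de = min(cfg.n_de, len(default_study["genes"]) // 2)
        assert len(da & db) == round(cfg.de_overlap_frac * n_de)
        inter = sorted(da & db)
        same = np.mean([np.sign(de[kd_a].loc[g, "log2fc"])
                        == np.sign(de[kd_b].loc[g, "log2fc"])
                        for g in inter])
        expected = round(cfg.de_same_sign_frac * len(inter)) / len(inter)
        assert same == pytest.approx(expected)

    def test_full_overlap_full_concordance(self, default_study):
        from damidscope import concordance

        cfg = SimConfig(seed=8, de_overlap_frac=1.0, de_same_sign_frac=1.0)
        truth = plant_truth(default_study["genome"], default_study["genes"],
                            cfg)
        _, de = simulate_expression(default_study["genes"], truth, cfg)
        rep = concordance(de[cfg.knockdowns[0]], de[cfg.knockdowns[1]])
        assert rep.pct_a_in_b == 100.0
        assert rep.same_direction_pct == 100.0

    def test_invalid_sign_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(de_same_sign_frac=1.2)
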