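"""Normalization, NB site testing and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from damidscope import (
    SimConfig,
    bh_adjust,
    digest_genome,
    estimate_size_factors,
    filter_low_counts,
    plant_truth,
    simulate_counts,
    simulate_genome,
    test_sites,
)
from damidscope.counts import CountTable
from damidscope.digest import SiteIndex


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = np.tile(np.arange(1, 101)[:, None], (1, 4))
        np.testing.assert_allclose(estimate_size_factors(m), 1.0)

    def test_doubled_sample_has_double_factor(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(500, 1))
        m = np.hstack([base, 2 * base, base])
        f = estimate_size_factors(m)
        assert abs(f[1] / f[0] - 2.0) < 1e-9

    def test_recovers_planted_library_factors(self, kis_stats):
        table = kis_stats["filtered"]
        f = estimate_size_factors(table.matrix)
        truth = table.samples["libsize"].to_numpy()
        f = f / np.exp(np.mean(np.log(f)))
        truth = truth / np.exp(np.mean(np.log(truth)))
        assert np.all(np.abs(f / truth - 1) < 0.05)

    def test_all_zero_sites_fall_back_with_warning(self):
        m = np.array([[0, 5], [3, 0], [0, 0]])
        with pytest.warns(UserWarning):
            f = estimate_size_factors(m)
        assert (f > 0).all()


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_pvalue_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _null_stats(seed=42, **kw):
    cfg = SimConfig(seed=seed, planted_log2fc=0.0, **kw)
    genome, genes, *_ = simulate_genome(cfg)
    truth = plant_truth(genome, genes, cfg)
    index = SiteIndex(digest_genome(genome))
    table = simulate_counts(index, truth, cfg, "kis")
    filtered, _ = filter_low_counts(table)
    return test_sites(filtered)


class TestCalibrationAndPower:
    def test_identical_roles_give_zero_log2fc_and_no_calls(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(300, 2))
        m = np.hstack([base, base])  # fusion == control exactly
        sites = pd.DataFrame({"chrom": "c1", "start": np.arange(300) * 100,
                              "end": np.arange(300) * 100 + 4,
                              "site_index": np.arange(300)})
        samples = pd.DataFrame({"sample": list("abcd"), "factor": "kis",
                                "role": ["fusion", "fusion",
                                         "dam_only", "dam_only"],
                                "replicate": [1, 2, 1, 2]})
        stats = test_sites(CountTable(sites=sites, samples=samples, matrix=m))
        np.testing.assert_allclose(stats["log2fc"], 0.0, atol=1e-9)
        assert not stats["significant"].any()

    def test_refuses_single_replicate(self):
        sites = pd.DataFrame({"chrom": "c1", "start": [0], "end": [4],
                              "site_index": [0]})
        samples = pd.DataFrame({"sample": ["a", "b"], "factor": "kis",
                                "role": ["fusion", "dam_only"],
                                "replicate": [1, 1]})
        table = CountTable(sites=sites, samples=samples,
                           matrix=np.array([[5, 5]]))
        with pytest.raises(ValueError, match="replicates"):
            test_sites(table)

    def test_null_simulation_is_calibrated(self):
        stats = _null_stats(seed=42)
        assert len(stats) >= 5000
        assert stats["significant"].mean() <= 0.02
        assert sps.kstest(stats["pvalue"], "uniform").pvalue > 0.01

    def test_scale_invariance_of_log2fc(self, kis_stats):
        table = kis_stats["filtered"]
        scaled = CountTable(sites=table.sites.copy(),
                            samples=table.samples.copy(),
                            matrix=table.matrix * np.array([3, 1, 1, 1]))
        a = test_sites(table)["log2fc"].to_numpy()
        b = test_sites(scaled)["log2fc"].to_numpy()
        assert np.abs(a - b).max() < 0.05

    def test_power_increases_with_effect_size(self):
        recalls = []
        for lfc in (1.0, 2.0):
            cfg = SimConfig(seed=11, planted_log2fc=lfc)
            genome, genes, *_ = simulate_genome(cfg)
            truth = plant_truth(genome, genes, cfg)
            index = SiteIndex(digest_genome(genome))
            table = simulate_counts(index, truth, cfg, "kis")
            filtered, mask = filter_low_counts(table)
            stats = test_sites(filtered)
            in_block = truth.bound_site_mask(index, "kis")[np.flatnonzero(mask)]
            recalls.append(stats["significant"].to_numpy()[in_block].mean())
        assert recalls[1] > recalls[0]

    def test_planted_log2fc_recovered_in_blocks(self, default_study, kis_stats):
        truth, index = default_study["truth"], default_study["index"]
        mask = kis_stats["mask"]
        in_block = truth.bound_site_mask(index, "kis")[np.flatnonzero(mask)]
        lfc = kis_stats["stats"]["log2fc"].to_numpy()
        assert abs(np.median(lfc[in_block]) - 2.0) < 0.3
        assert abs(np.median(lfc[~in_block])) < 0.1

    def test_label_permutation_preserves_null_rate(self):
        cfg = SimConfig(seed=5, planted_log2fc=0.0)
        genome, genes, *_ = simulate_genome(cfg)
        truth = plant_truth(genome, genes, cfg)
        index = SiteIndex(digest_genome(genome))
        table = simulate_counts(index, truth, cfg, "kis")
        filtered, _ = filter_low_counts(table)
        # swap one fusion with one dam_only label
        swapped = filtered.samples.copy()
        swapped.loc[[0, 2], "role"] = ["dam_only", "fusion"]
        stats = test_sites(CountTable(sites=filtered.sites.copy(),
                                      samples=swapped,
                                      matrix=filtered.matrix))
        assert stats["significant"].mean() <= 0.02


def test_agrees_with_independent_nb_framework(kis_stats):
    """Cross-check log2fc and calls against pydeseq2 on the same table."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    table = kis_stats["filtered"]
    sub = slice(0, 1200)
    counts = pd.DataFrame(table.matrix[sub].T,
                          index=table.samples["sample"].tolist())
    meta = pd.DataFrame({"role": table.samples["role"].tolist()},
                        index=table.samples["sample"].tolist())
    dds = DeseqDataSet(counts=counts, metadata=meta, design="~role",
                       quiet=True)
    dds.deseq2()
    res = DeseqStats(dds, contrast=["role", "fusion", "dam_only"],
                     quiet=True)
    res.summary()
    ours = kis_stats["stats"].iloc[sub]
    r = np.corrcoef(ours["log2fc"], res.results_df["log2FoldChange"])[0, 1]
    assert r > 0.95
    # significant sites should agree closely at padj < 0.01
    a = ours["significant"].to_numpy()
    b = ((res.results_df["padj"] < 0.01)
         & (res.results_df["log2FoldChange"] > 0)).to_numpy()
    agree = (a == b).mean()
    assert agree > 0.95
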