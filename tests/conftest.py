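"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from damidscope import (
    SimConfig,
    digest_genome,
    filter_low_counts,
    plant_truth,
    simulate_counts,
    simulate_genome,
    test_sites,
)
from damidscope.digest import SiteIndex


@pytest.fixture(scope="session")
def small_study():
    """One-chromosome study for fast unit checks."""
    cfg = SimConfig(seed=1, n_chroms=1, chrom_length=60_000, n_genes=8)
    genome, genes, features, enhancers = simulate_genome(cfg)
    truth = plant_truth(genome, genes, cfg)
    index = SiteIndex(digest_genome(genome))
    return {"config": cfg, "genome": genome, "genes": genes,
            "features": features, "enhancers": enhancers,
            "truth": truth, "index": index}


@pytest.fixture(scope="session")
def default_study():
    """Default-scale study: free blocks for kis, gene bodies for polii."""
    cfg = SimConfig(seed=42, factors=("kis", "polii"),
                    gene_targeted_factors=("polii",))
    genome, genes, features, enhancers = simulate_genome(cfg)
    truth = plant_truth(genome, genes, cfg)
    index = SiteIndex(digest_genome(genome))
    return {"config": cfg, "genome": genome, "genes": genes,
            "features": features, "enhancers": enhancers,
            "truth": truth, "index": index}


@pytest.fixture(scope="session")
def kis_stats(default_study):
    """Filtered counts and site statistics for the free-block factor."""
    cfg = default_study["config"]
    table = simulate_counts(default_study["index"], default_study["truth"],
                            cfg, "kis")
    filtered, mask = filter_low_counts(table)
    stats = test_sites(filtered)
    return {"table": table, "filtered": filtered, "mask": mask, "stats": stats}


def make_stats_frame(chrom_sig: dict[str, str], start0: int = 100,
                     spacing: int = 200) -> pd.DataFrame:
    """Build a minimal SiteStatTable from per-chromosome S/N patterns."""
    rows = []
    for chrom, pattern in chrom_sig.items():
        for i, ch in enumerate(pattern):
            start = start0 + i * spacing
            rows.append({
                "site_id": f"{chrom}:{start}", "chrom": chrom,
                "start": start, "end": start + 4, "site_index": i,
                "base_mean": 50.0, "log2fc": 2.0 if ch == "S" else 0.0,
                "pvalue": 1e-6 if ch == "S" else 0.5,
                "padj": 1e-4 if ch == "S" else 0.9,
                "significant": ch == "S",
            })
    return pd.DataFrame(rows)
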