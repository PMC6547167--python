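"""End-to-end orchestration: simulate -> digest -> count -> test -> calls -> views.

``run_all`` executes every stage from a single config mapping, writes the
standard output files into an output directory and returns a RunManifest
with per-stage row counts and checksums.  Re-running with the same config
overwrites the outputs deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from damidscope import io as dio
from damidscope.calls import call_bound_genes, call_occupancy, call_peaks
from damidscope.config import AnalysisParams, SimConfig
from damidscope.counts import CountTable, filter_low_counts
from damidscope.digest import SiteIndex, build_partition, classify_sites, digest_genome
from damidscope.genesets import (
    concordance,
    enriched_genes,
    expressed_genes,
    overlap_report,
)
from damidscope.simulate import (
    SimTruth,
    plant_truth,
    simulate_counts,
    simulate_expression,
    simulate_genome,
)
from damidscope.sitetest import test_sites
from damidscope.views import embed_sites, feature_distribution, intersect_retained, metaprofile

logger = logging.getLogger("damidscope")


@dataclass
class RunManifest:
    config: dict[str, Any]
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    seed: int = 0

    def record(self, path: str) -> None:
        with open(path, "rb") as fh:
            self.outputs[os.path.basename(path)] = hashlib.sha256(
                fh.read()).hexdigest()

    def validate(self) -> None:
        c = self.counts
        chain = [c.get("sites_digested", 0), c.get("sites_retained_max", 0)]
        if chain[1] > chain[0]:
            raise AssertionError("retained sites exceed digested sites")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def run_all(config: dict[str, Any] | None = None, outdir: str = "damidscope_run",
            embed: bool = False) -> RunManifest:
    """Run the full synthetic pipeline from one configuration mapping.

    ``config`` keys override SimConfig fields; an optional "params" block
    overrides AnalysisParams.  Set ``embed=True`` to also compute the
    UMAP co-occupancy embedding (needs >= 2 factors and is the slowest
    stage).
    """
    config = dict(config or {})
    params = AnalysisParams(**config.pop("params", {}))
    sim = SimConfig(**config)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config={**dataclasses.asdict(sim),
                                   "params": dataclasses.asdict(params)},
                           seed=sim.seed)

    logger.info("simulating genome (seed=%d)", sim.seed)
    genome, genes, features, enhancers = simulate_genome(sim)
    truth = plant_truth(genome, genes, sim)

    fasta = os.path.join(outdir, "genome.fa")
    dio.write_fasta(genome, fasta)
    gtf = os.path.join(outdir, "annotation.gtf")
    dio.write_gtf(genes, features, gtf)
    short = {"developmental": "dev", "housekeeping": "hk"}
    for label, df in enhancers.items():
        dio.write_bed(df, os.path.join(
            outdir, f"enhancers_{short.get(label, label)}.bed"))

    sites = digest_genome(genome)
    index = SiteIndex(sites)
    dio.write_bed(sites.rename(columns={"site_index": "name"}),
                  os.path.join(outdir, "gatc_sites.bed"))
    manifest.counts["sites_digested"] = len(sites)
    manifest.counts["genes"] = len(genes)

    sizes = {c: len(s) for c, s in genome.items()}
    partition = build_partition(genes, features, sizes)
    dio.write_bed(partition.as_frame(), os.path.join(outdir, "partition.bed"))
    assigned = classify_sites(sites, partition)

    stats_by_factor: dict[str, pd.DataFrame] = {}
    retained_max = 0
    for factor in sim.factors:
        table = simulate_counts(index, truth, sim, factor)
        dio.write_tsv(table.to_frame(), os.path.join(outdir, f"counts_{factor}.tsv"))
        dio.write_tsv(table.samples, os.path.join(outdir, f"samples_{factor}.tsv"))
        filtered, mask = filter_low_counts(table, params.min_mean_count)
        retained_max = max(retained_max, len(filtered.sites))
        stats = test_sites(filtered, params)
        stats_by_factor[factor] = stats
        dio.write_tsv(stats, os.path.join(outdir, f"site_stats_{factor}.tsv"))

        peaks = call_peaks(stats, params)
        dio.write_bed(
            peaks.assign(name=[f"{factor}_peak_{i}" for i in range(len(peaks))],
                         score=(-np.log10(np.maximum(peaks["min_padj"], 1e-300))
                                ).round(2) if len(peaks) else []),
            os.path.join(outdir, f"peaks_{factor}.bed"),
            columns=["chrom", "start", "end", "name", "score"])
        bound = call_bound_genes(stats, genes, params)
        dio.write_tsv(bound[["gene_id", "bound"]],
                      os.path.join(outdir, f"bound_genes_{factor}.tsv"))
        manifest.counts[f"significant_{factor}"] = int(stats["significant"].sum())
        manifest.counts[f"retained_{factor}"] = len(stats)
        manifest.counts[f"peaks_{factor}"] = len(peaks)
        manifest.counts[f"bound_genes_{factor}"] = int(bound["bound"].sum())
    manifest.counts["sites_retained_max"] = retained_max

    # Pol II-style occupancy on the first gene-targeted factor, if any
    for factor in sim.gene_targeted_factors:
        occ = call_occupancy(stats_by_factor[factor], genes, params,
                             seed=sim.seed + 7)
        dio.write_tsv(occ, os.path.join(outdir, f"occupancy_{factor}.tsv"))
        manifest.counts[f"active_genes_{factor}"] = int(occ["active"].sum())

    # signal views for the first factor
    first = sim.factors[0]
    stats0 = stats_by_factor[first]
    anchors = pd.DataFrame({"chrom": genes["chrom"], "pos": genes["tss"],
                            "strand": genes["strand"]})
    prof = metaprofile(stats0[["chrom", "start", "end"]],
                       stats0["log2fc"].to_numpy(), anchors)
    dio.write_tsv(prof, os.path.join(outdir, f"metaprofile_tss_{first}.tsv"))

    assigned_retained = assigned.merge(
        stats0[["chrom", "start", "significant"]], on=["chrom", "start"])
    if assigned_retained["significant"].any():
        dist = feature_distribution(assigned_retained,
                                    assigned_retained["significant"].to_numpy())
        dio.write_tsv(dist, os.path.join(outdir, f"feature_dist_{first}.tsv"))

    if embed and len(sim.factors) >= 2:
        joint = intersect_retained(stats_by_factor)
        emb = embed_sites(joint)
        dio.write_tsv(emb.coordinates, os.path.join(outdir, "embedding.tsv"))
        with open(os.path.join(outdir, "embedding_params.json"), "w") as fh:
            json.dump(emb.params, fh, indent=2)

    # expression integration
    rpkm, de_tables = simulate_expression(genes, truth, sim)
    dio.write_tsv(rpkm.reset_index(), os.path.join(outdir, "rpkm.tsv"))
    for kd, df in de_tables.items():
        dio.write_tsv(df.reset_index(), os.path.join(outdir, f"de_{kd}.tsv"))
    isc = sim.celltypes[0]
    expressed = expressed_genes(rpkm, isc)
    manifest.counts["expressed_genes"] = len(expressed)
    if len(sim.knockdowns) >= 2:
        rep = concordance(de_tables[sim.knockdowns[0]], de_tables[sim.knockdowns[1]],
                          *sim.knockdowns[:2])
        with open(os.path.join(outdir, "concordance.json"), "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({
            "expressed_genes": sorted(truth.expressed_genes),
            "bound_gene_truth": {k: sorted(v)
                                 for k, v in truth.bound_gene_truth.items()},
            "enriched_genes": {k: sorted(v) for k, v in truth.enriched_genes.items()},
            "de_truth": truth.de_truth,
            "bound_blocks": {k: v.to_dict(orient="records")
                             for k, v in truth.bound_blocks.items()},
        }, fh, indent=2, default=str)

    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path) and name != "manifest.json":
            manifest.record(path)
    manifest.validate()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest
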