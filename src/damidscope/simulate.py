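"""Synthetic DamID study generator with known planted structure.

Everything downstream is testable against the truth this module emits:
a multi-chromosome genome with GATC motifs at a target density,
non-overlapping genes with exons and UTRs, two enhancer classes,
per-factor bound blocks with a planted log2 enrichment, fusion vs
Dam-only replicate counts with negative-binomial noise and unequal
library sizes, read-level intervals, a three-cell-type rpkm table and a
pair of knockdown DE tables with planted overlap and sign concordance.
All draws are routed through seeds derived from ``SimConfig.seed``, so a
config determines its outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from damidscope.config import SimConfig
from damidscope.counts import CountTable, READ_COLUMNS
from damidscope.digest import SiteIndex, digest_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF = np.frombuffer(b"GATC", dtype=np.uint8)
_MIN_GAP = 700  # between genes; leaves room for enhancer placement


@dataclass
class SimTruth:
    """Planted structure of a simulated study.

    bound_blocks: per factor, a frame of (chrom, start, end, log2fc);
    expressed_genes: genes with ISC rpkm planted > 1; enriched_genes:
    per cell type, the genes satisfying the two-part enrichment rule;
    de_truth: per knockdown, gene -> planted sign of the fold change.
    """

    bound_blocks: dict[str, pd.DataFrame] = field(default_factory=dict)
    bound_gene_truth: dict[str, set[str]] = field(default_factory=dict)
    expressed_genes: set[str] = field(default_factory=set)
    enriched_genes: dict[str, set[str]] = field(default_factory=dict)
    de_truth: dict[str, dict[str, int]] = field(default_factory=dict)

    def bound_site_mask(self, index: SiteIndex, factor: str) -> np.ndarray:
        """Boolean mask over the digest: sites fully inside a bound block."""
        if factor not in self.bound_blocks:
            raise KeyError(f"factor {factor!r} has no planted blocks")
        mask = np.zeros(len(index), dtype=bool)
        for b in self.bound_blocks[factor].itertuples():
            mask[index.contained(str(b.chrom), int(b.start), int(b.end))] = True
        return mask

    def bound_genes(self, genes: pd.DataFrame, index: SiteIndex,
                    factor: str, min_sites: int = 2) -> set[str]:
        """Genes whose body contains >= min_sites consecutive planted sites."""
        mask = self.bound_site_mask(index, factor)
        out = set()
        for g in genes.itertuples():
            rows = index.contained(str(g.chrom), int(g.start), int(g.end))
            if len(rows) < min_sites:
                continue
            run = 0
            for r in rows:
                run = run + 1 if mask[r] else 0
                if run >= min_sites:
                    out.add(g.gene_id)
                    break
        return out


def _rng(config: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *tags])


def _scan_motif(arr: np.ndarray) -> np.ndarray:
    hits = (arr[:-3] == _MOTIF[0]) & (arr[1:-2] == _MOTIF[1]) \
        & (arr[2:-1] == _MOTIF[2]) & (arr[3:] == _MOTIF[3])
    return np.flatnonzero(hits)


def _make_chromosome(length: int, rate: float, rng: np.random.Generator) -> str:
    """Uniform-base sequence nudged to about length * rate GATC motifs."""
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    target = int(round(length * rate))
    for _ in range(30):
        starts = _scan_motif(arr)
        diff = target - len(starts)
        sd = max(np.sqrt(length * rate * (1 - rate)), 1.0)
        if abs(diff) <= sd:
            break
        if diff > 0:
            pos = rng.integers(0, length - 4, size=diff)
            for p in pos:
                arr[p:p + 4] = _MOTIF
        else:
            kill = rng.choice(starts, size=-diff, replace=False)
            repl = _BASES[rng.integers(0, 4, size=len(kill))]
            # mutate the motif's A; re-rolls that keep it are caught next pass
            arr[kill + 1] = repl
    return arr.tobytes().decode("ascii")


def _gene_structure(gene_start: int, length: int, strand: str, gene_id: str,
                    chrom: str, rng: np.random.Generator) -> list[dict]:
    """Exon/5'UTR/3'UTR features (genome coordinates, 0-based half-open)."""
    u5 = int(rng.integers(100, 301))
    u3 = int(rng.integers(100, 301))
    left_utr, right_utr = (u5, u3) if strand == "+" else (u3, u5)
    interior_lo = left_utr + 100
    interior_hi = length - right_utr - 100
    n_introns = int(rng.integers(1, 4))
    cuts = np.sort(rng.integers(interior_lo, interior_hi, size=2 * n_introns))
    introns = []
    for a, b in zip(cuts[0::2], cuts[1::2]):
        if b - a >= 50 and (not introns or a - introns[-1][1] >= 50):
            introns.append((int(a), int(b)))
    exons, prev = [], 0
    for a, b in introns:
        exons.append((prev, a))
        prev = b
    exons.append((prev, length))

    feats = [{"gene_id": gene_id, "feature": "exon", "chrom": chrom,
              "start": gene_start + a, "end": gene_start + b} for a, b in exons]
    utr5_rel = (0, left_utr) if strand == "+" else (length - right_utr, length)
    utr3_rel = (length - right_utr, length) if strand == "+" else (0, left_utr)
    feats.append({"gene_id": gene_id, "feature": "utr5", "chrom": chrom,
                  "start": gene_start + utr5_rel[0], "end": gene_start + utr5_rel[1]})
    feats.append({"gene_id": gene_id, "feature": "utr3", "chrom": chrom,
                  "start": gene_start + utr3_rel[0], "end": gene_start + utr3_rel[1]})
    return feats


def simulate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame,
                               dict[str, pd.DataFrame]]:
    """Genome, gene annotation and enhancer sets.

    Returns (genome, genes, features, enhancers) where enhancers maps
    'developmental' and 'housekeeping' to disjoint BED-like frames.
    Genes are non-overlapping, single-transcript, each with exons, a
    5'UTR, a 3'UTR, a strand and hence a TSS.
    """
    rng = _rng(config, 1)
    genome = {
        f"chr{i + 1}": _make_chromosome(config.chrom_length, config.gatc_rate, rng)
        for i in range(config.n_chroms)
    }

    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1

    gene_rows, feat_rows = [], []
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    gid = 0
    for ci, chrom in enumerate(genome):
        n = int(per_chrom[ci])
        gaps_by_chrom[chrom] = []
        if n == 0:
            gaps_by_chrom[chrom].append((0, config.chrom_length))
            continue
        lengths = rng.integers(*config.gene_length_range, size=n)
        needed = int(lengths.sum()) + (n + 1) * _MIN_GAP
        if needed > config.chrom_length:
            raise ValueError(
                f"chromosome of {config.chrom_length} bp too short for {n} genes: "
                f"needs >= {needed} bp (gene lengths + {_MIN_GAP} bp gaps)")
        slack = config.chrom_length - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for k in range(n):
            gap = _MIN_GAP + int(extra[k])
            gaps_by_chrom[chrom].append((pos, pos + gap))
            start = pos + gap
            end = start + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:04d}"
            gid += 1
            gene_rows.append({
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "start": start, "end": end,
                "tss": start if strand == "+" else end - 1,
            })
            feat_rows.extend(_gene_structure(start, int(lengths[k]), strand,
                                             gene_id, chrom, rng))
            pos = end
        gaps_by_chrom[chrom].append((pos, config.chrom_length))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand",
                                             "start", "end", "tss"])
    features = pd.DataFrame(feat_rows, columns=["gene_id", "feature", "chrom",
                                                "start", "end"])

    # one enhancer per intergenic gap, alternating classes
    all_gaps = [(c, a, b) for c, gaps in gaps_by_chrom.items() for a, b in gaps
                if b - a >= config.enhancer_length + 200]
    order = rng.permutation(len(all_gaps))
    enh_rows: dict[str, list[dict]] = {"developmental": [], "housekeeping": []}
    for slot, gi in enumerate(order):
        label = "developmental" if slot % 2 == 0 else "housekeeping"
        if len(enh_rows[label]) >= config.n_enhancers_per_class:
            continue
        c, a, b = all_gaps[gi]
        lo = a + 100
        hi = b - 100 - config.enhancer_length
        start = int(rng.integers(lo, hi + 1))
        enh_rows[label].append({"chrom": c, "start": start,
                                "end": start + config.enhancer_length,
                                "name": f"{label[:3]}_{len(enh_rows[label])}"})
    enhancers = {k: pd.DataFrame(v, columns=["chrom", "start", "end", "name"])
                 for k, v in enh_rows.items()}
    return genome, genes, features, enhancers


def _plant_blocks(index: SiteIndex, config: SimConfig, factor: str,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Free-standing bound blocks as runs of 4-8 consecutive GATC sites."""
    sites = index.sites
    n_sites = len(sites)
    target = int(round(config.frac_sites_bound * n_sites))
    used = np.zeros(n_sites, dtype=bool)
    chrom_arr = sites["chrom"].to_numpy()
    rows = []
    placed = 0
    attempts = 0
    while placed < target and attempts < 50 * max(target, 1):
        attempts += 1
        k = int(rng.integers(4, 9))
        i = int(rng.integers(0, max(n_sites - k, 1)))
        span = slice(i, i + k)
        if used[max(i - 1, 0): min(i + k + 1, n_sites)].any():
            continue
        if len(set(chrom_arr[span])) != 1:
            continue
        used[span] = True
        rows.append({
            "chrom": chrom_arr[i],
            "start": int(sites["start"].iloc[i]),
            "end": int(sites["end"].iloc[i + k - 1]),
            "log2fc": config.planted_log2fc,
        })
        placed += k
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2fc"])


def plant_truth(genome: dict[str, str], genes: pd.DataFrame,
                config: SimConfig) -> SimTruth:
    """Draw the planted structure: bound blocks, gene lists, DE truth."""
    rng = _rng(config, 2)
    index = SiteIndex(digest_genome(genome))
    truth = SimTruth()

    gene_ids = genes["gene_id"].tolist()
    pool = list(gene_ids)
    rng.shuffle(pool)
    n_enr = min(config.n_enriched_per_celltype, len(pool) // 3)
    for ct in config.celltypes:
        truth.enriched_genes[ct] = set(pool[:n_enr])
        pool = pool[n_enr:]

    isc = config.celltypes[0]
    n_expr = int(round(config.frac_genes_expressed * len(gene_ids)))
    expressed = set(truth.enriched_genes[isc])
    for g in pool:
        if len(expressed) >= n_expr:
            break
        expressed.add(g)
    truth.expressed_genes = expressed

    # bound blocks per factor.  Gene-targeted factors bind whole gene
    # bodies: the Pol II-style factor binds the expressed genes, any other
    # gene-targeted factor its own random gene subset; remaining factors
    # get free-standing site-run blocks.
    eligible = {g.gene_id for g in genes.itertuples()
                if len(index.contained(str(g.chrom), int(g.start), int(g.end))) >= 2}
    sizes = {c: len(s) for c, s in genome.items()}
    for fi, factor in enumerate(config.factors):
        frng = _rng(config, 3, fi)
        if factor in config.tss_factors:
            # promoter-style factor: a narrow block centred on the TSS of
            # every expressed gene (windows without a GATC site are inert)
            hw = config.tss_halfwidth
            rows = []
            for g in genes.itertuples():
                if g.gene_id not in expressed:
                    continue
                start = max(int(g.tss) - hw, 0)
                end = min(int(g.tss) + hw, sizes[str(g.chrom)])
                if len(index.contained(str(g.chrom), start, end)) >= 1:
                    rows.append({"chrom": g.chrom, "start": start, "end": end,
                                 "log2fc": config.planted_log2fc})
            truth.bound_blocks[factor] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "log2fc"])
        elif factor in config.gene_targeted_factors:
            if factor == config.polii_factor:
                targets = expressed & eligible
            else:
                pool_t = sorted(eligible)
                frng.shuffle(pool_t)
                n_t = int(round(config.frac_genes_bound * len(gene_ids)))
                targets = set(pool_t[:n_t])
            rows = [{"chrom": g.chrom, "start": int(g.start), "end": int(g.end),
                     "log2fc": config.planted_log2fc}
                    for g in genes.itertuples() if g.gene_id in targets]
            truth.bound_blocks[factor] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "log2fc"])
            truth.bound_gene_truth[factor] = targets
        else:
            truth.bound_blocks[factor] = _plant_blocks(index, config, factor, frng)

    # DE truth: overlapping deregulated sets with planted sign agreement
    if len(config.knockdowns) >= 2 and gene_ids:
        n_de = min(config.n_de, len(gene_ids) // 2)
        n_overlap = int(round(config.de_overlap_frac * n_de))
        shuffled = list(gene_ids)
        rng.shuffle(shuffled)
        overlap = shuffled[:n_overlap]
        rest = shuffled[n_overlap:]
        kd_a, kd_b = config.knockdowns[:2]
        only_a = rest[: n_de - n_overlap]
        only_b = rest[n_de - n_overlap: 2 * (n_de - n_overlap)]
        n_same = int(round(config.de_same_sign_frac * n_overlap))
        truth.de_truth[kd_a] = {}
        truth.de_truth[kd_b] = {}
        for j, g in enumerate(overlap):
            s = 1 if rng.random() < 0.5 else -1
            truth.de_truth[kd_a][g] = s
            truth.de_truth[kd_b][g] = s if j < n_same else -s
        for g in only_a:
            truth.de_truth[kd_a][g] = 1 if rng.random() < 0.5 else -1
        for g in only_b:
            truth.de_truth[kd_b][g] = 1 if rng.random() < 0.5 else -1

    # invariants
    sizes = {c: len(s) for c, s in genome.items()}
    for factor, blocks in truth.bound_blocks.items():
        for b in blocks.itertuples():
            if b.start < 0 or b.end > sizes[str(b.chrom)]:
                raise AssertionError(f"block outside {b.chrom} for {factor}")
    return truth


def sample_sheet(config: SimConfig, factor: str) -> pd.DataFrame:
    rows = []
    for r in range(config.n_reps_fusion):
        rows.append({"sample": f"{factor}_fusion_{r + 1}", "factor": factor,
                     "role": "fusion", "replicate": r + 1})
    for r in range(config.n_reps_control):
        rows.append({"sample": f"{factor}_dam_{r + 1}", "factor": factor,
                     "role": "dam_only", "replicate": r + 1})
    return pd.DataFrame(rows)


def _nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mu)
    return rng.negative_binomial(n, p)


def simulate_counts(index: SiteIndex, truth: SimTruth, config: SimConfig,
                    factor: str) -> CountTable:
    """NB counts for one factor's fusion and Dam-only replicates.

    Dam-only samples: NB(baseline_mean x library factor, dispersion).
    Fusion samples: the mean is multiplied by 2^log2fc at sites fully
    inside a bound block.  Library factors are drawn log-uniform within
    ``libsize_spread`` and recorded in the sample sheet.
    """
    if factor not in truth.bound_blocks:
        raise KeyError(f"factor {factor!r} has no planted truth")
    fi = list(config.factors).index(factor) if factor in config.factors else 99
    rng = _rng(config, 4, fi)
    sheet = sample_sheet(config, factor)

    lo, hi = config.libsize_spread
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sheet)))
    sheet["libsize"] = libs

    n_sites = len(index)
    base = np.full(n_sites, float(config.baseline_mean))
    fusion_mu = base.copy()
    blocks = truth.bound_blocks[factor]
    for b in blocks.itertuples():
        rows = index.contained(str(b.chrom), int(b.start), int(b.end))
        fusion_mu[rows] = base[rows] * (2.0 ** float(b.log2fc))

    matrix = np.zeros((n_sites, len(sheet)), dtype=np.int64)
    for j, row in sheet.iterrows():
        mu = (fusion_mu if row["role"] == "fusion" else base) * row["libsize"]
        matrix[:, j] = _nb_draw(mu, config.dispersion, rng)
    return CountTable(sites=index.sites.copy(), samples=sheet, matrix=matrix)


def simulate_reads(index: SiteIndex, truth: SimTruth, config: SimConfig,
                   factor: str, role: str = "fusion",
                   depth_scale: float = 1.0) -> pd.DataFrame:
    """Read-level aligned intervals (BED-like) for one sample.

    Per GATC site the number of reads is Poisson with mean proportional
    to the site's expected count; each read is ``read_length`` bp,
    anchored at the motif (start for '+', end for '-') so the extension
    rule re-assigns it to its source site.
    """
    fi = list(config.factors).index(factor) if factor in config.factors else 99
    rng = _rng(config, 5, fi, 0 if role == "fusion" else 1)
    mask = truth.bound_site_mask(index, factor)
    mu = np.full(len(index), float(config.baseline_mean))
    if role == "fusion":
        lfc = np.zeros(len(index))
        blocks = truth.bound_blocks[factor]
        for b in blocks.itertuples():
            lfc[index.contained(str(b.chrom), int(b.start), int(b.end))] = b.log2fc
        mu = mu * (2.0 ** lfc)
    mu = mu * depth_scale
    n_reads = rng.poisson(mu)
    if n_reads.sum() == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    sites = index.sites
    rows = np.repeat(np.arange(len(index)), n_reads)
    strands = np.where(rng.random(len(rows)) < 0.5, "+", "-")
    starts = np.where(
        strands == "+",
        sites["start"].to_numpy()[rows],
        np.maximum(sites["end"].to_numpy()[rows] - config.read_length, 0),
    )
    out = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy()[rows],
        "start": starts,
        "end": starts + config.read_length,
        "strand": strands,
    })
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_expression(genes: pd.DataFrame, truth: SimTruth, config: SimConfig
                        ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """rpkm table (genes x 3 cell types) and the knockdown DE table pair.

    Planted enriched genes satisfy the enrichment rule (>= 2x each other
    cell type, others < 2); planted expressed genes have reference-type
    rpkm > 1; all other genes violate at least one rule.  DE tables carry
    padj < 0.01 exactly for the planted deregulated genes, with log2fc
    signs following the planted concordance structure.
    """
    rng = _rng(config, 6)
    isc, ct2, ct3 = config.celltypes
    gene_ids = genes["gene_id"].tolist()
    rpkm = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"),
                        columns=list(config.celltypes))
    for g in gene_ids:
        if g in truth.enriched_genes.get(isc, set()):
            vals = {isc: rng.uniform(4.0, 40.0),
                    ct2: rng.uniform(0.1, 1.8), ct3: rng.uniform(0.1, 1.8)}
        elif g in truth.enriched_genes.get(ct2, set()):
            vals = {ct2: rng.uniform(4.0, 40.0),
                    isc: rng.uniform(0.1, 0.95), ct3: rng.uniform(0.1, 0.95)}
        elif g in truth.enriched_genes.get(ct3, set()):
            vals = {ct3: rng.uniform(4.0, 40.0),
                    isc: rng.uniform(0.1, 0.95), ct2: rng.uniform(0.1, 0.95)}
        elif g in truth.expressed_genes:
            # expressed but in no enriched set: all cell types >= 2
            vals = {isc: rng.uniform(2.1, 30.0),
                    ct2: rng.uniform(2.1, 8.0), ct3: rng.uniform(2.1, 8.0)}
        else:
            vals = {isc: rng.uniform(0.0, 0.95),
                    ct2: rng.uniform(2.1, 6.0), ct3: rng.uniform(2.1, 6.0)}
        for ct, v in vals.items():
            rpkm.loc[g, ct] = v

    de_tables = {}
    for kd in config.knockdowns:
        signs = truth.de_truth.get(kd, {})
        lfc = np.where(
            np.isin(gene_ids, list(signs)),
            0.0,  # filled below for deregulated genes
            rng.normal(0.0, 0.2, size=len(gene_ids)),
        )
        padj = rng.uniform(0.02, 1.0, size=len(gene_ids))
        df = pd.DataFrame({"log2fc": lfc, "padj": padj},
                          index=pd.Index(gene_ids, name="gene_id"))
        for g, s in signs.items():
            df.loc[g, "log2fc"] = s * rng.uniform(0.5, 3.0)
            df.loc[g, "padj"] = rng.uniform(1e-6, 0.009)
        de_tables[kd] = df
    return rpkm, de_tables
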