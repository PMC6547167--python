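"""Peaks, bound-gene calls and Pol II occupancy from site statistics.

Peaks merge runs of >= 2 consecutive significant GATC sites; a gene is
bound when 2 consecutive significant sites lie within its body; Pol II
occupancy averages per-site log2 (Dam-Pol II / Dam-only) ratios over each
gene's transcript span and assigns an FDR by site-label permutation.
"Consecutive" means adjacent in the ordered list of retained
(post-filter) sites on a chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from damidscope.config import AnalysisParams
from damidscope.sitetest import bh_adjust

PEAK_COLUMNS = ["chrom", "start", "end", "n_sites", "min_padj", "mean_log2fc"]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) positional slices."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def call_peaks(stats: pd.DataFrame, params: AnalysisParams | None = None,
               raw_adjacency: bool = False) -> pd.DataFrame:
    """Merge runs of >= min_consecutive_sites consecutive significant sites.

    Rows of ``stats`` are the retained sites in genomic order; adjacency
    is positional within each chromosome (``raw_adjacency=True`` instead
    requires the original site_index values to be consecutive, i.e. no
    filtered-out site in between).
    """
    params = params or AnalysisParams()
    peaks = []
    for chrom, sub in stats.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        sig = sub["significant"].to_numpy(bool)
        for i, j in _runs(sig):
            if raw_adjacency:
                idx = sub["site_index"].to_numpy()[i:j]
                breaks = np.flatnonzero(np.diff(idx) != 1)
                pieces = np.split(np.arange(i, j), breaks + 1)
            else:
                pieces = [np.arange(i, j)]
            for piece in pieces:
                if len(piece) < params.min_consecutive_sites:
                    continue
                block = sub.iloc[piece]
                peaks.append({
                    "chrom": chrom,
                    "start": int(block["start"].iloc[0]),
                    "end": int(block["end"].iloc[-1]),
                    "n_sites": len(block),
                    "min_padj": float(block["padj"].min()),
                    "mean_log2fc": float(block["log2fc"].mean()),
                })
    if not peaks:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    return pd.DataFrame(peaks).sort_values(["chrom", "start"]).reset_index(drop=True)


def call_bound_genes(stats: pd.DataFrame, genes: pd.DataFrame,
                     params: AnalysisParams | None = None,
                     mode: str = "sites") -> pd.DataFrame:
    """Classify each gene as bound or not.

    mode="sites" (default): bound iff >= 2 consecutive significant sites
    whose motifs lie fully within [gene_start, gene_end); evidence records
    the (site_index, site_index) pairs.  mode="peaks": bound iff a peak
    from ``call_peaks`` overlaps the gene body by >= 1 bp.
    """
    params = params or AnalysisParams()
    need = params.min_consecutive_sites
    by_chrom = {
        str(c): sub.sort_values("start").reset_index(drop=True)
        for c, sub in stats.groupby("chrom", sort=False)
    }
    peaks = call_peaks(stats, params) if mode == "peaks" else None

    rows = []
    for g in genes.itertuples():
        sub = by_chrom.get(str(g.chrom))
        evidence: list[tuple[int, int]] = []
        bound = False
        if sub is None:
            rows.append({"gene_id": g.gene_id, "bound": False, "evidence": []})
            continue
        if mode == "peaks":
            p = peaks[(peaks["chrom"] == g.chrom)
                      & (peaks["start"] < g.end) & (peaks["end"] > g.start)]
            bound = len(p) > 0
            evidence = list(zip(p["start"].tolist(), p["end"].tolist()))
        else:
            starts = sub["start"].to_numpy()
            lo = np.searchsorted(starts, g.start, side="left")
            hi = np.searchsorted(starts, g.end - 3, side="left")
            inside = sub.iloc[lo:hi]
            sig = inside["significant"].to_numpy(bool)
            for i, j in _runs(sig):
                if j - i >= need:
                    idx = inside["site_index"].to_numpy()[i:j]
                    evidence.extend(
                        [(int(idx[k]), int(idx[k + 1])) for k in range(len(idx) - 1)])
            bound = len(evidence) > 0
        rows.append({"gene_id": g.gene_id, "bound": bound, "evidence": evidence})
    return pd.DataFrame(rows)


def call_occupancy(stats: pd.DataFrame, genes: pd.DataFrame,
                   params: AnalysisParams | None = None,
                   n_permutations: int = 10_000,
                   seed: int = 0) -> pd.DataFrame:
    """Gene-level Pol II occupancy from per-site log2 ratios.

    Per gene: the mean log2 (fusion / Dam-only) ratio over retained sites
    within its transcript span.  Significance of mean > 0 comes from a
    one-sided site-label permutation null (ratios shuffled across sites,
    gene means recomputed each shuffle), BH-FDR over testable genes, and
    an active flag at fdr < polii_fdr.  Genes with no retained site are
    flagged untestable and excluded from testing.
    """
    params = params or AnalysisParams()
    rng = np.random.default_rng(seed)
    by_chrom = {
        str(c): sub.sort_values("start").reset_index(drop=True)
        for c, sub in stats.groupby("chrom", sort=False)
    }

    gene_sites: list[np.ndarray] = []
    testable: list[bool] = []
    means: list[float] = []
    # flatten ratios with per-chrom offsets
    flat = []
    start_of = {}
    for chrom, sub in by_chrom.items():
        start_of[chrom] = len(flat)
        flat.extend(sub["log2fc"].tolist())
    flat = np.asarray(flat)

    for g in genes.itertuples():
        sub = by_chrom.get(str(g.chrom))
        if sub is None:
            gene_sites.append(np.empty(0, dtype=int))
            testable.append(False)
            means.append(np.nan)
            continue
        starts = sub["start"].to_numpy()
        lo = np.searchsorted(starts, g.start, side="left")
        hi = np.searchsorted(starts, g.end - 3, side="left")
        idx = np.arange(lo, hi) + start_of[str(g.chrom)]
        gene_sites.append(idx)
        testable.append(len(idx) > 0)
        means.append(float(flat[idx].mean()) if len(idx) else np.nan)

    testable_arr = np.asarray(testable)
    obs = np.asarray(means)

    pvals = np.full(len(genes), np.nan)
    if testable_arr.any() and len(flat):
        order = np.concatenate([g for g, t in zip(gene_sites, testable_arr) if t])
        lengths = np.asarray([len(g) for g, t in zip(gene_sites, testable_arr) if t])
        bounds = np.concatenate([[0], np.cumsum(lengths)])[:-1]
        obs_t = obs[testable_arr]
        exceed = np.zeros(len(lengths))
        for _ in range(n_permutations):
            perm = flat[rng.permutation(len(flat))]
            sums = np.add.reduceat(perm[order], bounds)
            exceed += (sums / lengths) >= obs_t
        pvals_t = (1.0 + exceed) / (n_permutations + 1.0)
        pvals[testable_arr] = pvals_t

    fdr = np.full(len(genes), np.nan)
    if testable_arr.any():
        fdr[testable_arr] = bh_adjust(pvals[testable_arr])

    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "mean_log2_ratio": obs,
        "n_sites": [len(g) for g in gene_sites],
        "pvalue": pvals,
        "fdr": fdr,
        "active": np.where(testable_arr, fdr < params.polii_fdr, False),
        "testable": testable_arr,
    })
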