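"""From aligned read intervals to the GATC-site x sample count table.

Alignments are extended in their 3' direction to 300 nt or the first GATC
site, whichever comes first; coverage is then counted per 4-bp motif
(a read covers a site if the extended interval overlaps it by >= 1 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from damidscope.digest import SiteIndex

READ_COLUMNS = ["chrom", "start", "end", "strand"]
ROLES = ("fusion", "dam_only")


@dataclass
class CountTable:
    """Site x sample methylation-coverage counts.

    ``sites`` keeps the digest frame (chrom, start, end, site_index) in
    genomic order; ``samples`` is the sample sheet (sample, factor, role,
    replicate); ``matrix`` is int counts with one row per site and one
    column per sample, aligned with both frames.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites x samples")
        if (self.matrix < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.samples["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def role_columns(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.samples["role"] == role).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        for j, name in enumerate(self.samples["sample"]):
            df[name] = self.matrix[:, j]
        return df


def extend_reads(reads: pd.DataFrame, index: SiteIndex, cap: int = 300,
                 motif_inclusive: bool = True,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Extend each alignment 3'-ward to ``cap`` nt or the first GATC site.

    For a + read the end moves right to min(start + cap, far edge of the
    first motif at/after the read end); for a - read the start moves left
    symmetrically.  Reads already >= cap bp are unchanged.  With
    ``motif_inclusive`` (default) the terminating motif itself is covered,
    so the stopping site is counted; set False for motif-exclusive stops.
    """
    out = reads.reset_index(drop=True).copy()
    starts = out["start"].to_numpy(np.int64).copy()
    ends = out["end"].to_numpy(np.int64).copy()
    for chrom, sub in out.groupby("chrom", sort=False):
        site_starts = index.starts(str(chrom))  # raises on unknown chrom
        site_ends = site_starts + 4
        rows = sub.index.to_numpy()
        plus = sub["strand"].to_numpy() != "-"
        short = (ends[rows] - starts[rows]) < cap

        rp = rows[plus & short]
        if len(rp):
            capped = starts[rp] + cap
            nxt = np.searchsorted(site_starts, ends[rp], side="left")
            stop = np.where(
                nxt < len(site_starts),
                (site_ends if motif_inclusive else site_starts)[
                    np.minimum(nxt, len(site_starts) - 1)],
                np.iinfo(np.int64).max,
            )
            new_end = np.minimum(capped, np.maximum(stop, ends[rp]))
            if chrom_sizes is not None:
                new_end = np.minimum(new_end, chrom_sizes[str(chrom)])
            ends[rp] = np.maximum(new_end, ends[rp])

        rm = rows[~plus & short]
        if len(rm):
            capped = ends[rm] - cap
            # first motif wholly at/preceding the read start, scanning leftward
            prv = np.searchsorted(site_ends, starts[rm], side="right") - 1
            stop = np.where(
                prv >= 0,
                (site_starts if motif_inclusive else site_ends)[np.maximum(prv, 0)],
                np.iinfo(np.int64).min,
            )
            new_start = np.maximum(capped, np.minimum(stop, starts[rm]))
            new_start = np.maximum(new_start, 0)
            starts[rm] = np.minimum(new_start, starts[rm])

    out["start"] = starts
    out["end"] = ends
    return out


def count_coverage(reads: pd.DataFrame, index: SiteIndex) -> np.ndarray:
    """Count, per GATC site, the reads overlapping its motif by >= 1 bp."""
    counts = np.zeros(len(index), dtype=np.int64)
    for chrom, sub in reads.groupby("chrom", sort=False):
        site_starts = index.starts(str(chrom))
        rows = index.rows(str(chrom))
        rs = sub["start"].to_numpy(np.int64)
        re = sub["end"].to_numpy(np.int64)
        lo = np.searchsorted(site_starts, rs - 3, side="left")
        hi = np.searchsorted(site_starts, re, side="left")
        # increment counts[rows[lo:hi]] for every read via a difference array
        diff = np.zeros(len(site_starts) + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        counts[rows] += np.cumsum(diff[:-1])
    return counts


def assemble_count_table(per_sample_reads: dict[str, pd.DataFrame],
                         samples: pd.DataFrame, index: SiteIndex,
                         cap: int = 300) -> CountTable:
    """Extend and count each sample's reads into one CountTable."""
    matrix = np.zeros((len(index), len(samples)), dtype=np.int64)
    for j, name in enumerate(samples["sample"]):
        extended = extend_reads(per_sample_reads[name], index, cap=cap)
        matrix[:, j] = count_coverage(extended, index)
    return CountTable(sites=index.sites.copy(), samples=samples.copy(), matrix=matrix)


def filter_low_counts(table: CountTable, min_mean: float = 5.0
                      ) -> tuple[CountTable, np.ndarray]:
    """Discard sites averaging fewer than ``min_mean`` raw counts.

    The mean is taken across all samples of the comparison (fusion and
    Dam-only pooled) on raw counts.  Retained sites keep their original
    site_index so downstream consecutiveness bookkeeping stays valid.
    Returns (filtered table, boolean retained mask over input sites).
    """
    if min_mean < 0:
        raise ValueError("min_mean must be non-negative")
    mask = table.matrix.mean(axis=1) >= min_mean
    filtered = CountTable(
        sites=table.sites.loc[mask].reset_index(drop=True),
        samples=table.samples.copy(),
        matrix=table.matrix[mask],
    )
    return filtered, mask
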