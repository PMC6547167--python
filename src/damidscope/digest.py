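"""GATC-site digestion and the disjoint genomic-feature partition.

The 4-bp GATC motif is the unit of DamID resolution.  ``digest_genome``
locates every occurrence; ``build_partition`` converts a gene annotation
into five disjoint interval sets (5'UTR, 3'UTR, exon, intron, intergenic)
that tile the genome exactly; ``classify_sites`` assigns each site the
label of the interval containing its start coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

SITE_COLUMNS = ["chrom", "start", "end", "site_index"]
PARTITION_LABELS = ("utr5", "utr3", "exon", "intron", "intergenic")


def digest_genome(genome: Mapping[str, str],
                  chroms: Iterable[str] | None = None) -> pd.DataFrame:
    """Scan sequences for GATC motifs.

    Returns a frame with chrom, start, end (= start + 4) and site_index,
    the 0-based rank of the site on its chromosome.  GATC cannot overlap
    itself, so a left-to-right scan finds every occurrence exactly once.
    ``chroms`` optionally restricts the scan (assembled chromosomes only).
    """
    use = list(genome) if chroms is None else [c for c in chroms if c in genome]
    records = []
    for chrom in use:
        seq = genome[chrom].upper()
        starts = []
        pos = seq.find("GATC")
        while pos != -1:
            starts.append(pos)
            pos = seq.find("GATC", pos + 4)
        starts_arr = np.asarray(starts, dtype=np.int64)
        records.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts_arr,
            "end": starts_arr + 4,
            "site_index": np.arange(len(starts_arr), dtype=np.int64),
        }))
    if not records:
        return pd.DataFrame(columns=SITE_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "site_index": np.int64})
    return pd.concat(records, ignore_index=True)


class SiteIndex:
    """Per-chromosome sorted arrays of site coordinates for interval queries."""

    def __init__(self, sites: pd.DataFrame):
        self.sites = sites.reset_index(drop=True)
        self._starts: dict[str, np.ndarray] = {}
        self._rows: dict[str, np.ndarray] = {}
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            self._starts[str(chrom)] = sub["start"].to_numpy()
            self._rows[str(chrom)] = sub.index.to_numpy()

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def starts(self, chrom: str) -> np.ndarray:
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} was not digested")
        return self._starts[chrom]

    def rows(self, chrom: str) -> np.ndarray:
        if chrom not in self._rows:
            raise KeyError(f"chromosome {chrom!r} was not digested")
        return self._rows[chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global row indices of sites overlapping [start, end) by >= 1 bp."""
        s = self.starts(chrom)
        lo = np.searchsorted(s, start - 3, side="left")
        hi = np.searchsorted(s, end, side="left")
        return self.rows(chrom)[lo:hi]

    def contained(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global row indices of sites whose 4-bp motif lies fully inside."""
        s = self.starts(chrom)
        lo = np.searchsorted(s, start, side="left")
        hi = np.searchsorted(s, end - 3, side="left")
        return self.rows(chrom)[lo:hi]


def _to_ranges(df: pd.DataFrame) -> pr.PyRanges:
    if len(df) == 0:
        return pr.PyRanges(pd.DataFrame({"Chromosome": [], "Start": [], "End": []}))
    return pr.PyRanges(pd.DataFrame({
        "Chromosome": df["chrom"].to_numpy(),
        "Start": df["start"].to_numpy(),
        "End": df["end"].to_numpy(),
    }))


def _from_ranges(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64})
    out = pd.DataFrame({
        "chrom": df["Chromosome"].astype(str).to_numpy(),
        "start": df["Start"].to_numpy(np.int64),
        "end": df["End"].to_numpy(np.int64),
    })
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class FeaturePartition:
    """Disjoint labeled interval sets tiling the genome.

    ``intervals`` maps each label in PARTITION_LABELS to a sorted frame of
    disjoint (chrom, start, end) rows; together the five sets cover every
    base of every chromosome exactly once.
    """

    intervals: dict[str, pd.DataFrame]
    chrom_sizes: dict[str, int]
    _lookup: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False)

    def total_length(self, label: str) -> int:
        df = self.intervals[label]
        return int((df["end"] - df["start"]).sum())

    def as_frame(self) -> pd.DataFrame:
        parts = []
        for label in PARTITION_LABELS:
            df = self.intervals[label].copy()
            df["name"] = label
            parts.append(df)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["chrom", "start"]).reset_index(drop=True)

    def _build_lookup(self) -> None:
        self._lookup = {}
        frame = self.as_frame()
        for chrom, sub in frame.groupby("chrom", sort=False):
            self._lookup[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["name"].to_numpy(),
            )

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Label of the partition interval containing each position."""
        if self._lookup is None:
            self._build_lookup()
        if chrom not in self._lookup:
            raise KeyError(f"chromosome {chrom!r} not in partition")
        if np.any(positions >= self.chrom_sizes[chrom]) or np.any(positions < 0):
            raise ValueError(f"position beyond chromosome {chrom!r} bounds")
        starts, labels = self._lookup[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        return labels[idx]


def build_partition(genes: pd.DataFrame, features: pd.DataFrame,
                    chrom_sizes: Mapping[str, int],
                    precedence: tuple[str, str, str] = ("utr5", "utr3", "exon"),
                    ) -> FeaturePartition:
    """Partition the genome into 5'UTR / 3'UTR / exon / intron / intergenic.

    Overlapping records of each feature class are merged, then the classes
    are made disjoint by sequential subtraction in ``precedence`` order;
    introns are the gene spans minus all exonic/UTR sequence, and
    intergenic is the genome minus the gene spans.
    """
    # annotation consistency: exons/UTRs must lie inside their gene span
    if len(features):
        spans = genes.set_index("gene_id")
        for f in features.itertuples():
            try:
                g = spans.loc[f.gene_id]
            except KeyError:
                raise ValueError(f"feature references unknown gene {f.gene_id!r}")
            if f.start < g["start"] or f.end > g["end"]:
                raise ValueError(
                    f"{f.feature} outside gene span for gene {f.gene_id!r}")

    def merged(label: str) -> pr.PyRanges:
        sub = features[features["feature"] == label] if len(features) else features
        return _to_ranges(sub).merge() if len(sub) else _to_ranges(
            pd.DataFrame(columns=["chrom", "start", "end"]))

    genic = _to_ranges(genes).merge() if len(genes) else _to_ranges(
        pd.DataFrame(columns=["chrom", "start", "end"]))
    whole = pr.PyRanges(pd.DataFrame({
        "Chromosome": list(chrom_sizes),
        "Start": [0] * len(chrom_sizes),
        "End": [chrom_sizes[c] for c in chrom_sizes],
    }))

    raw = {label: merged(label) for label in precedence}
    out: dict[str, pd.DataFrame] = {}
    claimed = None
    for label in precedence:
        g = raw[label]
        if claimed is not None and len(g) and len(claimed):
            g = g.subtract(claimed)
        out[label] = _from_ranges(g)
        claimed = g if claimed is None or not len(claimed) else pr.PyRanges(
            pd.concat([claimed.df, g.df], ignore_index=True)).merge()

    exonic_all = pr.PyRanges(pd.concat(
        [raw[l].df for l in precedence if len(raw[l])], ignore_index=True)
    ).merge() if any(len(raw[l]) for l in precedence) else _to_ranges(
        pd.DataFrame(columns=["chrom", "start", "end"]))

    intron = genic.subtract(exonic_all) if len(genic) and len(exonic_all) else genic
    out["intron"] = _from_ranges(intron)
    intergenic = whole.subtract(genic) if len(genic) else whole
    out["intergenic"] = _from_ranges(intergenic)

    part = FeaturePartition(intervals={l: out[l] for l in PARTITION_LABELS},
                            chrom_sizes=dict(chrom_sizes))
    total = sum(part.total_length(l) for l in PARTITION_LABELS)
    expected = sum(chrom_sizes.values())
    if total != expected:
        raise AssertionError(
            f"partition does not tile the genome ({total} != {expected} bp)")
    return part


def classify_sites(sites: pd.DataFrame, partition: FeaturePartition) -> pd.DataFrame:
    """Assign each GATC site the feature label at its start coordinate."""
    out = sites.reset_index(drop=True).copy()
    labels = np.empty(len(out), dtype=object)
    for chrom, sub in out.groupby("chrom", sort=False):
        labels[sub.index.to_numpy()] = partition.label_at(
            str(chrom), sub["start"].to_numpy())
    out["feature"] = labels
    return out
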