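"""Readers and writers for the plain-text genomics formats the pipeline uses.

All in-memory coordinates are 0-based half-open.  GTF is converted on
import (1-based inclusive on disk) and on export; BED passes through.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from pyfaidx import Fasta

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]
FEATURE_COLUMNS = ["gene_id", "feature", "chrom", "start", "end"]

# on-disk GTF feature names <-> internal labels
_GTF_FEATURE = {"exon": "exon", "5UTR": "utr5", "3UTR": "utr3"}
_GTF_FEATURE_INV = {v: k for k, v in _GTF_FEATURE.items()}


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA into an uppercase name -> sequence dict."""
    with Fasta(path, rebuild=True, as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(genes: pd.DataFrame, features: pd.DataFrame, path: str,
              source: str = "damidscope") -> None:
    """Write gene/transcript/exon/5UTR/3UTR records, 1-based inclusive."""
    lines = []
    feats = features.set_index("gene_id") if len(features) else features
    for g in genes.itertuples():
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f'gene_id "{g.gene_id}";'
        )
        lines.append(
            f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        if len(features):
            sub = feats.loc[[g.gene_id]] if g.gene_id in feats.index else feats.iloc[0:0]
            for f in sub.itertuples():
                name = _GTF_FEATURE_INV[f.feature]
                lines.append(
                    f"{f.chrom}\t{source}\t{name}\t{f.start + 1}\t{f.end}\t.\t{g.strand}\t.\t{attrs}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _parse_gtf_attr(attr: str, key: str) -> str | None:
    for part in attr.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def read_gtf(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Import gene spans and exon/UTR features from a GTF.

    Only gene, exon, 5UTR and 3UTR records are retained; coordinates are
    converted to 0-based half-open.  Returns (genes, features) frames.
    """
    raw = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attribute"],
        dtype={"chrom": str},
    )
    raw["gene_id"] = raw["attribute"].map(lambda a: _parse_gtf_attr(a, "gene_id"))
    raw["start"] = raw["start"] - 1  # to 0-based half-open

    g = raw[raw["feature"] == "gene"]
    genes = pd.DataFrame({
        "gene_id": g["gene_id"].to_numpy(),
        "chrom": g["chrom"].to_numpy(),
        "strand": g["strand"].to_numpy(),
        "start": g["start"].to_numpy(),
        "end": g["end"].to_numpy(),
    })
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"] - 1)

    f = raw[raw["feature"].isin(_GTF_FEATURE)]
    features = pd.DataFrame({
        "gene_id": f["gene_id"].to_numpy(),
        "feature": f["feature"].map(_GTF_FEATURE).to_numpy(),
        "chrom": f["chrom"].to_numpy(),
        "start": f["start"].to_numpy(),
        "end": f["end"].to_numpy(),
    })
    return genes.reset_index(drop=True), features.reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in ["chrom", "start", "end", "name", "score", "strand"]
                       if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str, names: list[str] | None = None) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=names or base[:3])
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = (names or base)[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
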