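"""Expression-derived gene lists and binding/expression set statistics.

List rules: a gene is expressed when its rpkm in the reference cell type
is strictly > 1; it is enriched in a cell type when its rpkm there is at
least 2x the rpkm in each other cell type AND every other cell type's
rpkm is < 2.  Overlap reports give |A|, |B|, |A∩B| and directional
percentages; concordance adds the same-sign fraction of two
differential-expression tables' shared deregulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSetReport:
    """Sizes, intersection and directional percentages of two gene sets."""

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    intersection: int
    pct_a_in_b: float
    pct_b_in_a: float
    same_direction_pct: float | None = None
    venn: tuple[int, int, int] = (0, 0, 0)  # |A-B|, |A∩B|, |B-A|
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "size_a": self.size_a, "size_b": self.size_b,
            "intersection": self.intersection,
            "pct_a_in_b": self.pct_a_in_b, "pct_b_in_a": self.pct_b_in_a,
            "same_direction_pct": self.same_direction_pct,
            "venn": list(self.venn), "note": self.note,
        }


def expressed_genes(rpkm: pd.DataFrame, celltype: str,
                    threshold: float = 1.0) -> set[str]:
    """Genes with rpkm strictly above ``threshold`` in ``celltype``."""
    if celltype not in rpkm.columns:
        raise KeyError(f"cell type {celltype!r} not in rpkm table")
    sel = rpkm[rpkm[celltype] > threshold]
    return set(sel.index.astype(str))


def enriched_genes(rpkm: pd.DataFrame, celltype: str) -> set[str]:
    """Genes enriched in ``celltype`` under the two-part rule.

    (1) rpkm in ``celltype`` >= 2x the rpkm in each other cell type
    (non-strict); (2) rpkm in each other cell type < 2 (strict).  A gene
    with zero rpkm in the target cell type is never enriched (otherwise an
    all-zero row would satisfy the >=2x condition for every cell type at once).
    """
    if celltype not in rpkm.columns:
        raise KeyError(f"cell type {celltype!r} not in rpkm table")
    others = [c for c in rpkm.columns if c != celltype]
    target = rpkm[celltype]
    cond = target > 0
    for o in others:
        cond &= target >= 2.0 * rpkm[o]
        cond &= rpkm[o] < 2.0
    return set(rpkm.index[cond].astype(str))


def differentiated_genes(rpkm: pd.DataFrame,
                         differentiated: tuple[str, str] = ("EE", "EC")) -> set[str]:
    """Union of the enriched sets of the differentiated cell types."""
    out: set[str] = set()
    for ct in differentiated:
        out |= enriched_genes(rpkm, ct)
    return out


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


def overlap_report(set_a: set[str], set_b: set[str],
                   label_a: str = "A", label_b: str = "B") -> GeneSetReport:
    """Intersection and directional percentage report for two gene sets."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return GeneSetReport(
        label_a=label_a, label_b=label_b,
        size_a=len(a), size_b=len(b), intersection=len(inter),
        pct_a_in_b=_pct(len(inter), len(a)),
        pct_b_in_a=_pct(len(inter), len(b)),
        venn=(len(a - b), len(inter), len(b - a)),
    )


def deregulated_set(de: pd.DataFrame, padj_threshold: float = 0.01) -> set[str]:
    """Genes with adjusted p-value below threshold in a DE table."""
    if not de["padj"].between(0, 1).all():
        raise ValueError("padj values must lie in [0, 1]")
    return set(de.index[de["padj"] < padj_threshold].astype(str))


def concordance(de_a: pd.DataFrame, de_b: pd.DataFrame,
                label_a: str = "A", label_b: str = "B",
                padj_threshold: float = 0.01) -> GeneSetReport:
    """Overlap of two DE tables' deregulated genes plus sign concordance.

    Same-direction fraction over the intersection, with sign(log2fc) = 0
    its own category (matching only itself) so zero fold changes cannot
    silently inflate concordance.  Genes missing from one table count as
    not deregulated there.
    """
    da, db = deregulated_set(de_a, padj_threshold), deregulated_set(de_b, padj_threshold)
    report = overlap_report(da, db, label_a, label_b)
    inter = sorted(da & db)
    if inter:
        sa = np.sign(de_a.loc[inter, "log2fc"].to_numpy())
        sb = np.sign(de_b.loc[inter, "log2fc"].to_numpy())
        report.same_direction_pct = round(100.0 * float((sa == sb).mean()), 1)
    else:
        report.same_direction_pct = None
        report.note = "empty intersection; concordance undefined"
    return report


def bound_and_deregulated(bound: set[str], de: pd.DataFrame,
                          label_bound: str = "bound",
                          padj_threshold: float = 0.01) -> GeneSetReport:
    """Cross binding calls with a DE table, both directions reported.

    pct_a_in_b = percent of deregulated genes that are bound;
    pct_b_in_a = percent of bound genes that are deregulated.  With no
    deregulated genes both percentages are reported as 0 with a note.
    """
    dereg = deregulated_set(de, padj_threshold)
    report = overlap_report(dereg, set(bound), "deregulated", label_bound)
    if not dereg:
        report.note = "no deregulated genes; percentages reported as 0"
    return report
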