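"""Configuration objects shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds applied downstream of counting.

    Defaults are the conventions of the analysis this package implements:
    sites are significant at BH-adjusted p < 0.01 with positive log2
    enrichment, sites averaging fewer than 5 counts are discarded, peaks
    and bound genes require 2 consecutive significant sites, Pol II
    occupancy calls use FDR < 0.01, and reads are extended up to 300 nt.
    """

    padj_threshold: float = 0.01
    min_mean_count: float = 5.0
    min_consecutive_sites: int = 2
    polii_fdr: float = 0.01
    extension_cap: int = 300

    def __post_init__(self) -> None:
        if self.padj_threshold <= 0 or self.polii_fdr <= 0:
            raise ValueError("significance thresholds must be positive")
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be non-negative")
        if self.min_consecutive_sites < 1:
            raise ValueError("min_consecutive_sites must be >= 1")
        if self.extension_cap <= 0:
            raise ValueError("extension_cap must be positive")


DEFAULT_FACTORS = ("kis", "trr")
DEFAULT_CELLTYPES = ("ISC", "EE", "EC")
DEFAULT_KNOCKDOWNS = ("kis_kd", "trr_kd")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic DamID study.

    The simulator emulates a targeted DamID experiment: a small
    multi-chromosome genome with GATC motifs, non-overlapping genes with
    exons and UTRs, two enhancer classes, per-factor planted bound blocks
    with a known log2 enrichment, fusion vs Dam-only replicate counts with
    negative-binomial noise and unequal library sizes, a three-cell-type
    rpkm table and a pair of knockdown differential-expression tables with
    planted overlap and sign concordance.

    ``gene_targeted_factors`` lists factors (Pol II style) whose bound
    blocks are the bodies of the planted expressed genes rather than
    free-standing site runs.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    gatc_rate: float = 1.0 / 256.0
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    n_enhancers_per_class: int = 25
    enhancer_length: int = 400
    factors: tuple[str, ...] = DEFAULT_FACTORS
    gene_targeted_factors: tuple[str, ...] = ()
    tss_factors: tuple[str, ...] = ()
    tss_halfwidth: int = 50
    polii_factor: str = "polii"
    frac_genes_bound: float = 0.3
    frac_sites_bound: float = 0.10
    planted_log2fc: float = 2.0
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    n_reps_fusion: int = 2
    n_reps_control: int = 2
    libsize_spread: tuple[float, float] = (0.5, 2.0)
    read_length: int = 75
    celltypes: tuple[str, ...] = DEFAULT_CELLTYPES
    knockdowns: tuple[str, ...] = DEFAULT_KNOCKDOWNS
    frac_genes_expressed: float = 0.5
    n_enriched_per_celltype: int = 15
    n_de: int = 60
    de_overlap_frac: float = 0.5
    de_same_sign_frac: float = 0.8

    def __post_init__(self) -> None:
        for name in ("frac_sites_bound", "de_overlap_frac", "de_same_sign_frac",
                     "frac_genes_expressed", "frac_genes_bound"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10,000 bp")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be >= 0")
        if self.n_reps_fusion < 2 or self.n_reps_control < 2:
            raise ValueError("need >= 2 replicates per role")
        if len(self.celltypes) != 3:
            raise ValueError("exactly three cell types are required")
        lo, hi = self.libsize_spread
        if not (0 < lo <= hi):
            raise ValueError("libsize_spread must be 0 < lo <= hi")
        unknown = (set(self.gene_targeted_factors) | set(self.tss_factors)) \
            - set(self.factors)
        if unknown:
            raise ValueError(f"targeted factors not in factors: {sorted(unknown)}")
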