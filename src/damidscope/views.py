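"""Metaprofiles, feature distributions and the chromatin-state embedding.

Metaprofiles average per-site log2 enrichment in distance bins around
oriented anchors (TSSs, enhancer centers).  Feature distributions report
the fraction of a site subset falling in each genomic feature class.
The embedding places GATC sites in 2-D with UMAP from their multi-factor
log2 enrichment profiles (n_neighbors=30, min_dist=0.0, n_components=2,
metric='canberra', random_state=42 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from damidscope.digest import PARTITION_LABELS

EMBED_DEFAULTS = {
    "n_neighbors": 30,
    "min_dist": 0.0,
    "n_components": 2,
    "metric": "canberra",
    "random_state": 42,
}


def metaprofile(sites: pd.DataFrame, values: np.ndarray, anchors: pd.DataFrame,
                window: int = 2_000, binsize: int = 50) -> pd.DataFrame:
    """Mean signal in distance bins around oriented anchors.

    ``sites`` carries chrom/start/end of retained GATC sites, ``values``
    the per-site log2 enrichment, ``anchors`` chrom/pos and optionally
    strand ('+' assumed when absent, as for enhancer centers).  A site
    contributes its value to the bin containing (site midpoint - anchor),
    sign-flipped on '-' anchors so bins read 5'->3', for every anchor
    whose +/- window contains it.  Bins with no contribution are NaN.
    """
    if window % binsize != 0:
        raise ValueError("window must be an integer multiple of binsize")
    values = np.asarray(values, dtype=float)
    if len(values) != len(sites):
        raise ValueError("one value per site required")
    n_bins = 2 * window // binsize
    total = np.zeros(n_bins)
    total_sq = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)

    mids = ((sites["start"].to_numpy() + sites["end"].to_numpy()) // 2)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order_sites = sites.reset_index(drop=True)
    for chrom, sub in order_sites.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        by_chrom[str(chrom)] = (mids[rows], values[rows])

    has_strand = "strand" in anchors.columns
    for a in anchors.itertuples():
        entry = by_chrom.get(str(a.chrom))
        if entry is None:
            continue
        m, v = entry
        pos = int(a.pos)
        lo = np.searchsorted(m, pos - window, side="left")
        hi = np.searchsorted(m, pos + window, side="left")
        if hi <= lo:
            continue
        d = m[lo:hi] - pos
        if has_strand and a.strand == "-":
            d = -d
        keep = (d >= -window) & (d < window)
        b = ((d[keep] + window) // binsize).astype(int)
        vv = v[lo:hi][keep]
        np.add.at(total, b, vv)
        np.add.at(total_sq, b, vv ** 2)
        np.add.at(count, b, 1)

    centers = np.arange(n_bins) * binsize - window + binsize / 2.0
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        var = np.where(count > 1,
                       (total_sq - total ** 2 / np.maximum(count, 1))
                       / np.maximum(count - 1, 1), np.nan)
    return pd.DataFrame({"bin_center": centers, "mean": mean,
                         "sd": np.sqrt(np.maximum(var, 0.0)), "n": count})


def profile_flatness(profile: pd.DataFrame, alpha: float = 0.05
                     ) -> tuple[bool, float, float]:
    """Family-wise test that a metaprofile has no positional structure.

    Per non-empty bin, z = (bin mean - pooled mean) / bin SE; the profile
    is flat when no |z| exceeds the two-sided Sidak critical value at
    family level ``alpha``.  (A fixed per-bin 2-SE cut would reject a
    truly flat profile with probability ~1 - 0.95^n_bins.)  Returns
    (flat, max |z|, critical value).
    """
    from scipy import stats as sps

    ok = profile["n"].to_numpy() > 1
    mean = profile["mean"].to_numpy()[ok]
    n = profile["n"].to_numpy()[ok]
    sd = profile["sd"].to_numpy()[ok]
    # pooled within-bin variance: per-bin sd at small n is a poor scale
    # and would make z a heavy-tailed t statistic
    sd_pooled = np.sqrt(np.sum((n - 1) * sd ** 2) / max(np.sum(n - 1), 1))
    pooled = np.average(mean, weights=n)
    z = (mean - pooled) / np.maximum(sd_pooled / np.sqrt(n), 1e-12)
    crit = sps.norm.isf((1 - (1 - alpha) ** (1 / max(len(z), 1))) / 2)
    return bool(np.all(np.abs(z) <= crit)), float(np.max(np.abs(z))), float(crit)


def feature_distribution(assigned: pd.DataFrame,
                         subset: np.ndarray | None = None,
                         subset_name: str = "subset") -> pd.DataFrame:
    """Per-feature fractions of a site subset, with optional background.

    ``assigned`` must carry a 'feature' column (from classify_sites);
    ``subset`` is a boolean mask over its rows (default: all sites, which
    then doubles as its own background with enrichment ratio 1).
    """
    labels = list(PARTITION_LABELS)
    feats = assigned["feature"].to_numpy()
    if subset is None:
        subset = np.ones(len(assigned), dtype=bool)
    subset = np.asarray(subset, dtype=bool)
    if subset.sum() == 0:
        raise ValueError(f"site subset {subset_name!r} is empty")
    sub_counts = pd.Series(feats[subset]).value_counts()
    bg_counts = pd.Series(feats).value_counts()
    frac = np.array([sub_counts.get(l, 0) for l in labels], dtype=float)
    frac /= frac.sum()
    bg = np.array([bg_counts.get(l, 0) for l in labels], dtype=float)
    bg /= bg.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg > 0, frac / bg, np.nan)
    return pd.DataFrame({"feature": labels, "fraction": frac,
                         "background": bg, "enrichment": ratio})


@dataclass
class EmbeddingResult:
    """2-D UMAP coordinates plus the parameter record and factor overlays."""

    coordinates: pd.DataFrame  # site_id, x, y, one overlay column per factor
    params: dict = field(default_factory=dict)
    factors: tuple[str, ...] = ()


def embed_sites(log2_matrix: pd.DataFrame, **overrides) -> EmbeddingResult:
    """UMAP embedding of GATC sites from their multi-factor log2 profiles.

    ``log2_matrix`` has one row per site (index = site id) and one column
    per factor, complete (sites retained in every factor); parameter
    overrides are merged over the defaults.  The per-factor input values
    are exported alongside the coordinates as overlays.
    """
    import umap  # deferred: numba jit makes this import expensive

    params = {**EMBED_DEFAULTS, **overrides}
    if log2_matrix.isna().any().any():
        raise ValueError(
            "log2 matrix contains missing values; intersect sites across "
            "factors (or impute) before embedding")
    if len(log2_matrix) < params["n_neighbors"] + 1:
        raise ValueError("need more sites than n_neighbors to embed")
    reducer = umap.UMAP(**params)
    coords = reducer.fit_transform(log2_matrix.to_numpy(dtype=np.float32))
    out = pd.DataFrame({
        "site_id": log2_matrix.index.to_numpy(),
        "x": coords[:, 0],
        "y": coords[:, 1],
    })
    for col in log2_matrix.columns:
        out[col] = log2_matrix[col].to_numpy()
    return EmbeddingResult(coordinates=out, params=params,
                           factors=tuple(log2_matrix.columns))


def intersect_retained(stats_by_factor: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Site x factor log2 matrix over sites retained in ALL factors.

    The <5-mean-count filter is applied per factor, so the joint matrix
    UMAP needs is the intersection of each factor's retained sites.
    """
    mats = []
    for factor, stats in stats_by_factor.items():
        s = stats.set_index("site_id")["log2fc"].rename(factor)
        mats.append(s)
    joint = pd.concat(mats, axis=1, join="inner")
    return joint
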