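# Methods

## Scope and data model

All internal coordinates are 0-based half-open; GTF is converted on
import/export (1-based inclusive on disk), BED passes through. The unit
of measurement is the GATC motif (4 bp, non-self-overlapping, so a single
left-to-right scan finds every occurrence). Sites are indexed per
chromosome in ascending start order; "consecutive" downstream always
means adjacent in the ordered list of *retained* (post-filter) sites on a
chromosome, because filtered-out sites were never testable
(`raw_adjacency=True` restores strict site-index adjacency).

## Read extension and counting

An alignment is extended in its 3′ direction to 300 nt or the first GATC
site, whichever comes first: for a + read the new end is
min(start + 300, far edge of the first motif starting at/after the read
end); − reads extend the start leftward symmetrically. The terminating
motif is included by default (Dam methylates the GATC itself, and
inclusion makes read-level and count-level simulation consistent);
`motif_inclusive=False` gives the motif-exclusive variant. A site's count
is the number of extended reads overlapping its 4-bp interval by ≥1 bp.
The <5-mean-count filter is applied to raw counts across all samples of
one factor's comparison (fusion and Dam-only pooled), before
normalization — the conservative placement for a filter that precedes the
differential test. Duplicate reads are not collapsed.

## Feature partition

The annotation is reduced to gene, exon, 5′UTR and 3′UTR records, each
class merged, then made disjoint by sequential subtraction with
precedence 5′UTR > 3′UTR > exon; introns are gene spans minus all
exonic/UTR sequence and intergenic is the genome minus gene spans (all
interval algebra via pyranges). The five sets provably tile the genome
(asserted at construction). A site is classified by the label at its
*start* coordinate — deterministic, single-base intersect semantics; at
4 bp the difference from maximal-overlap assignment is negligible.

## Per-site negative-binomial test

Counts for site *s*, sample *j* are modelled NB with mean
`mu_sj = s_j * q_s(role_j)` and dispersion `alpha_s`
(Var = mu + alpha mu²).

* **Size factors** — median-of-ratios over sites with all-positive
  counts. Because planted (or real) enrichment sits in the fusion
  samples only, a single pass is composition-biased (≈ −0.12 background
  log2fc at 10% bound sites); after the first fit the factors are
  re-estimated on sites not called enriched (padj ≥ 0.1 or log2fc ≤ 0)
  and the model is refit once. Under a null table this refinement is a
  no-op.
* **Dispersion** — a per-site method-of-moments estimate from squared
  residuals around the fitted group means. The expectation of the
  residual sum is linear in alpha, `E[RSS] = A + B alpha`, where A and B
  account exactly (to first order) for the degrees of freedom absorbed by
  each group mean at arbitrary library sizes; B is additionally corrected
  for the plug-in bias `E[mu_hat²] = mu²(1 + relvar(q_hat))` by two
  fixed-point passes. Without these corrections alpha is underestimated
  ~2.5× at 2+2 replicates with a 4× library-size spread, which destroys
  p-value calibration. The mean–dispersion trend is a log-log lowess over
  moment estimates pooled in ~20 mean-quantile bins (per-site moment
  estimates at 2 residual df are frequently zero or negative, so pooling
  must precede the log). Each site's alpha is the trend/per-site blend
  with weight df_resid/(df_resid + prior_df), prior_df = 20: at low
  replication the trend dominates, which is what makes low-replicate NB
  testing stable.
* **Test** — each group mean is the NB MLE (Newton on the score; the
  ratio estimate Σk/Σs is the start and the fixed point when library
  sizes are equal), Wald statistic
  `z = (ln q_fusion − ln q_control) / sqrt(1/I_f + 1/I_c)` with
  `I_g = Σ_j mu_gj/(1 + alpha mu_gj)`, two-sided normal p-value, BH
  adjustment over all retained sites of the comparison. Significance is
  the conjunction padj < 0.01 AND log2fc > 0 (a two-sided test with a
  post-hoc sign requirement, matching the stated rule).
* **Effect size** — the reported log2fc is
  `log2((m_fusion + c)/(m_control + c))` on normalized counts with
  pseudocount c = 0.5, a simple documented moderation that shrinks toward
  0 at low counts; the exact variance stabilization of external NB
  frameworks is not replicated bit-for-bit (a cross-check test shows
  r > 0.95 agreement with one on a shared table).

Measured behaviour at the default study conditions (mean 50, alpha 0.1,
2+2 replicates): the null simulation (seed 42) gives a significant-site
fraction of 0 and KS uniformity p ≈ 0.39; the per-site power inside
planted log2fc = 2 blocks is ≈ 0.75, which is the information limit —
the Cramér–Rao SE of the per-site log-ratio at these conditions is
≥ 0.33, so z ≈ 4.1 against a BH threshold of z ≈ 3.4. Whole-gene
recovery is far easier (many sites per gene) and reaches ≥ 97%.

## Peaks, bound genes, occupancy

Peaks are maximal runs of ≥2 consecutive significant sites (each member
must satisfy both the padj and the sign condition); runs never cross
chromosomes and peaks never share sites. A gene is bound when two
consecutive significant sites lie fully within [gene_start, gene_end),
strand-agnostic; `mode="peaks"` instead asks whether any peak overlaps
the body by ≥1 bp (the two modes coincide when evidence sites are
intragenic). Pol II occupancy is the mean per-site log2 ratio over
retained sites in the gene span; significance of mean > 0 uses a
site-label permutation null (default 10,000 seeded shuffles of the ratio
vector with gene means recomputed each shuffle — distribution-free and
reproducible), BH-FDR over testable genes, active at FDR < 0.01. Genes
with no retained site are flagged untestable. A site inside two
overlapping genes counts for both.

## Metaprofiles, feature distribution, embedding

Metaprofiles bin (site midpoint − anchor) in anchor-oriented coordinates
(± window 2,000 bp, 50-bp bins — typical metagene defaults, configurable;
window/bin are not externally prescribed). Sites contribute to every
anchor whose window contains them; empty bins are NaN, not 0. The
flatness check for a profile (`profile_flatness`) compares each bin mean
to the pooled mean in units of pooled-variance standard errors against a
Šidák family-level critical value: a fixed per-bin 2-SE cut would reject
a truly flat 80-bin profile with probability ≈ 1 − 0.95⁸⁰ ≈ 0.98, and
per-bin sample SDs at n ≈ 10 would make the statistic heavy-tailed.

The embedding is UMAP on the site × factor log2 matrix restricted to
sites retained in *all* factors (the filter is per-factor, so the joint
matrix is the intersection), with n_neighbors=30, min_dist=0.0,
n_components=2, metric='canberra', random_state=42. Coordinates are
reproducible under the fixed seed on one platform; cross-platform
guarantees are neighbourhood-level, so quality is asserted via k-nearest-
neighbour label purity, not coordinates.

## Gene lists and integration

Expressed: rpkm strictly > 1 in the reference cell type. Enriched in a
cell type: rpkm ≥ 2× each other type (non-strict, reading "at least 2
times higher" literally) AND each other type < 2 (strict); a zero-rpkm
gene is never enriched (otherwise an all-zero row satisfies the >=2x condition
for all three types simultaneously and the enriched sets would not be
disjoint). The differentiated set is the union of the EE- and EC-enriched
lists. DE tables: deregulated at padj < 0.01 (strict); genes absent from
a table count as not deregulated so overlap denominators stay defined;
sign(0) is its own category in concordance so zero fold changes cannot
inflate agreement. Percentages are reported to one decimal.

## The simulator

What it emulates: a small multi-chromosome genome (default 3 × 500 kb)
with uniform base composition nudged to the target GATC density (1/256
by default — the uniform-sequence expectation); non-overlapping
single-transcript genes (120 by default, 2–6 kb) with exons, UTRs,
strands and TSSs; two disjoint enhancer classes in intergenic gaps;
per-factor bound blocks at a planted log2fc (default 2); NB counts
(Dam-only mean 50, dispersion 0.1, 2 fusion + 2 control replicates,
library factors log-uniform in [0.5, 2] so normalization must work);
read-level intervals anchored at motifs so the extension rule re-assigns
them; an rpkm table whose planted expressed/enriched genes satisfy the
list rules exactly and whose other genes provably violate one; and two
DE tables with planted overlap (50% of 60 genes) and sign concordance
(80%). Defaults are desk-scale and detection-friendly: the acceptance
quantity is parameter recovery, not biological realism.

Three planting modes: free-standing blocks are runs of 4–8 consecutive
GATC sites (every block covers ≥2 sites, so the 2-consecutive-site rules
are exercisable by construction); gene-targeted factors bind whole gene
bodies (the Pol II-style factor binds the planted expressed genes, any
other gene-targeted factor a random 30% gene subset recorded in
`bound_gene_truth`); promoter-style factors (`tss_factors`) bind a
±50 bp window at each expressed gene's TSS — one profile bin, so the
planted metaprofile maximum genuinely sits at the anchor.

What it does **not** emulate: sequencing error, PCR duplicates,
mappability heterogeneity, overlapping or multi-isoform genes, GC bias,
biological replicate heterogeneity beyond library size. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated model, not performance on real libraries.

Determinism: every draw flows through `numpy` Generators seeded from
`(config.seed, stage tag)`; identical configs give byte-identical FASTA,
GTF, BED and TSV outputs, and the pipeline manifest records SHA-256
checksums of everything it writes.

## Problem sizes and runtime

Default analyses use ~5,900 sites × 4 samples, 120 genes, and 10,000
permutations for occupancy; the full test suite and the acceptance
script each complete in well under a minute apart from UMAP, whose first
call costs ~30 s of JIT compilation. These sizes were chosen so that the
calibration experiments (≥5,000 retained sites for KS uniformity,
≥500 in-block sites for power) have adequate resolution.

## Known limitations

* P-value calibration at 2+2 replicates is excellent but not exact: the
  size factors are themselves estimated from 4 samples, and their error
  induces a small global shift in the log-ratios; across random seeds the
  null KS-uniformity p-value occasionally dips below 0.01 (observed 1 in
  5 seeds, minimum ≈ 0.005) with the significant-site rate still 0.
* The per-site Wald test is asymptotic in counts, not replicates; below
  mean ~15 the normal reference grows conservative.
* The permutation FDR for occupancy has resolution 1/(n_permutations+1);
  genes needing p < 1e-4 require raising `n_permutations`.
* `estimate_size_factors` falls back to total-count ratios when no site
  has all-positive counts (very sparse tables), which is not robust to
  composition effects.
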