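# Methods

`ptjoint` analyzes droplet-based joint single-cell profiles of a histone
modification and the transcriptome measured in the same nuclei. This
note documents the statistical model behind each stage, the synthetic
data the package tests itself against, and the numerical and design
choices a maintainer would want to know about.

## The analysis workflow

The workflow mirrors how joint histone + RNA droplet data are analyzed
in practice:

1. **Per-cell QC and pairing.** The DNA modality is summarized per
   barcode by its unique (deduplicated, barcode-aware) fragment count
   and FRiP — the fraction of a cell's fragments overlapping at least
   one peak, each fragment counted once however many peaks it touches.
   The peak set for FRiP comes from an initial pooled peak call. The RNA
   modality is summarized by UMI totals, detected genes and
   mitochondrial/ribosomal fractions. Cells passing both filters are
   paired by barcode intersection; barcodes whose UMI total exceeds
   `factor x median` (default 2) are flagged as likely doublets and
   removed from both modalities. This count heuristic deliberately
   replaces simulation-based doublet scoring: it is transparent and
   dependency-free, and under an additive doublet model its recall at
   factor 2 is intrinsically near 0.55 (the threshold sits almost
   exactly at the doublet-total median), which is the trade documented
   with it.
2. **Clustering.** RNA: counts-per-10k log1p normalization, most
   dispersed genes (default top 2,500), truncated SVD (default 35
   components), k-means. Chromatin: cell x 5-kb-bin counts with midpoint
   assignment (each fragment lands once in the bin containing its
   midpoint, so row sums equal per-cell fragment counts exactly),
   two-step TF-IDF `log(1 + 1e4 * TF * IDF)` with
   `IDF = n_cells / (1 + document frequency)`, top 85% of bins by total
   count, truncated SVD with the first (depth-correlated) component
   dropped, k-means. K-means on the embedding is the deterministic,
   tested path; graph-based clustering can be layered on through the
   same LabelMap interface. The TF-IDF variant is the log-scaled form
   used throughout chromatin single-cell analysis; it is exactly
   invariant to scaling any cell's counts.
3. **Concordance.** Each epigenome cluster is annotated by the
   plurality transcriptome type of its cells (ties break toward the
   larger transcriptome cluster, then lexicographically). Per
   transcriptome cluster i the overlap coefficient is
   `O_i = max_x |A_i ∩ B_x| / |A_i|` over epigenome clusters B_x on the
   common barcode set. For cross-dataset comparisons through a
   coembedding C, `O_ij = max_k min(|A_i ∩ C_k|/|A_i|, |B_j ∩ C_k|/|B_j|)`:
   query cluster i and reference cluster j agree to the extent both
   concentrate in one shared coembedding cluster.
4. **Peaks.** Pseudo-bulk insertion coverage treats each fragment end
   as a Tn5 insertion site, extended to a 150-bp window centered on the
   site (shift −75, extsize 150) and accumulated on a 10-bp step grid;
   total mass is `2 x n_fragments x extsize / step` up to edge clipping.
   Each bin's (rounded) depth is tested against a one-sided Poisson
   upper tail with `lambda = max(genome-wide expected depth, local
   10-kb mean)`; Benjamini–Hochberg q-values below 0.01 define
   significant bins, merged into peaks across gaps of at most 100 bp
   (narrow mode) or 1,000 bp (broad mode, used for the repressive mark's
   domain-scale enrichment). The summit is the maximum-coverage bin.
   Replicate-level calls are merged by the reproducibility rule: a peak
   is kept iff it overlaps peaks from at least two distinct replicates,
   kept summits are extended to a fixed 500-bp width, and overlapping
   extended intervals collapse keeping the summit of the call with the
   smallest q-value. Peak BEDs from an external caller can be supplied
   instead; the merging rule, not the caller, is the bespoke step.
5. **cCRE signal and modules.** Cluster-level signal is RPKM:
   `count / (interval kb x group fragments / 1e6)`. cCREs are proximal
   iff they intersect ±2 kb of any TSS, else distal. Retention requires
   RPKM strictly above 1 in at least one cluster with ≥ 100 nuclei.
   Retained cCREs of one class are row-normalized (unit sum, so modules
   reflect cell-type specificity rather than absolute signal) and
   factorized with NMF; a cCRE's module is the argmax of its loading
   row, ties to the lower module id. The default module count is 8 at
   the synthetic scale (configurable; at atlas scale 20 is typical).
6. **cCRE–gene linkage.** Candidates are distal cCREs within 500 kb of
   a gene's TSS. A co-occupancy prefilter replaces graphical-lasso
   co-accessibility with a transparent score: cells are grouped into
   within-cluster metacells of 20, the binarized (count > 0) per-cell
   signal at the distal cCRE and at the gene's TSS ± 2 kb anchor is
   averaged per metacell, and pairs with Pearson correlation > 0.1
   across metacells are retained (the 0.1 threshold is the load-bearing
   choice; the estimator is pluggable and the filter can be disabled).
   The linkage statistic is Spearman's correlation (SCC) between the
   cCRE's RPKM and the gene's mean log-normalized expression across
   pseudo-bulk columns. The null shuffles cell identities at the read
   level: each cCRE's fragment count is reallocated across pseudo-bulk
   groups by a multinomial proportional to group sequencing depth (the
   exact aggregate of giving every read a random cell), and each gene's
   UMI total is reallocated across cells proportional to library size;
   both matrices are rebuilt and SCCs recomputed, pooling
   `n_shuffles x n_pairs` background values (default 10 shuffles). A
   normal distribution fitted to the background (moment estimates mu0,
   sigma0) sets the cutoff: the estimated FDR at threshold s is
   `n_obs * P_N(X >= s) / #{observed >= s}`, monotonized by a running
   minimum so it never increases as the threshold rises, and the cutoff
   is the smallest observed score whose estimate falls below the
   nominal FDR (0.05). The active mark uses the upper tail (positive
   links), the repressive mark the lower tail (negative links). The
   two-sample Kolmogorov–Smirnov D between observed and background
   summarizes how far real links sit from the null.

   Two resolution choices matter here. First, SCC columns default to
   cluster x replicate pseudo-bulks rather than clusters alone: with K
   cell types and R replicates the correlation is estimated over K·R
   points instead of K, and with small K (the synthetic default is 8)
   the K-point Spearman null is so coarse (sd 1/sqrt(K−1) ≈ 0.38) that
   no attainable score clears an FDR of 0.05; the cluster-only mode
   remains available (`linkage_by_replicate=False`). Second, the null
   must be read-level: permuting labels across whole cells preserves
   cluster-composition fluctuations that couple both modalities for any
   profile-aligned pair, inflating the fitted null (measured mu0 ≈
   +0.15, sigma0 ≈ 0.31 at this scale) until no discovery survives;
   read-level reallocation leaves only counting noise, which is what
   the fitted-normal cutoff presupposes.
7. **Saturation.** For each grid size n, sample n barcodes without
   replacement, re-call peaks on their fragments and record the
   fraction of the full peak set overlapped. The cutoff is the smallest
   grid point reaching the recovery target (default 85%). Recovery at
   full depth is 1 by construction when the full set comes from the
   same caller and parameters.

## The synthetic data generator

The generator is first-class, tested code; its defaults define the
study conditions every downstream stage is validated against.

Default conditions: one 10-Mb chromosome; 8 cell types x 100 cells x 3
replicates (round-robin); 50 genes with non-overlapping bodies; 240
cCREs of 500 bp (30% proximal, i.e. within ±2 kb of a TSS); 40 planted
distal cCRE→gene links at 5–500 kb; per-cell fragments and UMIs
log-normal with median 2,000 and log-sd 0.35; target FRiP 0.5;
negative-binomial expression with gamma-Poisson dispersion 0.15; marker
fold change 8 (three markers per type); 5% doublets (each merging two
random singlet profiles; expected totals ≈ 2x a singlet); 5% duplicate
records to exercise barcode-aware deduplication. Fragment lengths
follow a four-component normal mixture at the subnucleosomal /
mono / di / trinucleosomal modes (60, 200, 400, 600 bp; sd 15% of the
mode); the repressive mark uses heavier mono/di/tri weights
(0.1/0.4/0.3/0.2 versus 0.45/0.35/0.15/0.05), reflecting the more
compact chromatin it marks. Size bands in the analysis sit at
multiples of the 147-bp nucleosomal unit, with the tri band extended
to 735 bp so the 600-bp mode classifies as trinucleosomal.

Expression programs: every gene gets a per-type log-normal multiplier
(sd 1.0) over a log-normal baseline. Marker genes have their own-type
multiplier set to `fold x max(other types)`, so the marker fold change
holds regardless of the draws. Planted-link target genes instead
receive a permuted geometric ladder (ratio 2) across types — a graded,
unambiguous cross-type ranking. This is the "strong coupling" the
linkage stage is meant to recover: the active mark's weight at a
planted distal cCRE is proportional to the target gene's per-type
abundance (linear coupling), and the repressive mark is the rowwise
reflection `max + min − w`, whose rank correlation with the active
profile is exactly −1 across types.

Three constructions keep the planted links *identifiable*, i.e. make
false-discovery accounting against the planted list meaningful:

- **Type-uniform unlinked distal cCREs.** If unlinked elements carried
  their own random type profiles, chance alignments with nearby genes
  would be genuine correlations of the generative model —
  indistinguishable in principle from planted links — and the planted
  list would not define a null. With uniform profiles, planted links
  are the only systematic distal-cCRE-to-gene covariation.
- **Neighborhood profile decorrelation.** Genes whose TSSs lie within
  twice the link window (1 Mb) can share candidate cCREs, so their
  final per-type abundance profiles are kept at pairwise |Spearman|
  ≤ 0.4 by greedy resampling (in normalized-profile space, where the
  per-type normalization acts; the cap relaxes to the quantization
  floor `1.6/(K−1)` when few types make it unattainable). Without the
  cap, a planted cCRE correlates genuinely with any neighbor gene whose
  profile chance-aligns with its target's.
- **Per-type mass balancing.** Within-type read allocation normalizes
  each type's total cCRE weight to one. If type-specific elements left
  those totals unequal, every type-uniform element would inherit the
  shared inverse-total profile — a common mode masquerading as
  cross-type signal. Row rescaling (which changes only overall element
  strength, never cross-type shape) equalizes the totals for both the
  activity matrix and the gene abundances; every linked gene is also
  guaranteed one proximal cCRE, since a detectable link needs a marked
  promoter anchor for the co-occupancy prescreen.

What the generator does **not** emulate: sequence-level reads, ambient
RNA, batch effects beyond per-replicate depth factors, empty droplets
(no cell-calling stage is needed), continuous or hierarchical cell
states, and correlated biological noise between the two modalities
within a cell beyond the shared type identity. Passing tests therefore
demonstrate that the statistics behave as designed under a clean
generative model; they do not certify performance on tissue data, where
the co-occupancy estimator, QC thresholds and the doublet heuristic
would all need empirical tuning.

## Numerical choices and edge cases

- All coordinates are 0-based half-open everywhere; writers never emit
  1-based coordinates. Dedup key is (chrom, start, end, barcode) with
  counts collapsed to 1; output sorted by that key.
- Spearman uses average ranks for ties and returns NaN for constant
  vectors; NaN pairs are excluded from observed and background pools
  symmetrically.
- The fitted-normal FDR needs ≥ 100 background values and a positive
  background sd; with no achievable threshold the significant set is
  empty and the minimum achievable FDR is reported.
- Peak calling is fully deterministic; BH is applied across all bins
  genome-wide. Local background includes the peak itself (a
  conservative choice for broad domains).
- TF-IDF and RNA normalization reject all-zero cells with an error
  instructing prior filtering, rather than silently imputing.
- Ties: top-bin selection breaks by genomic order; NMF module argmax
  breaks toward the lower module id; epigenome-cluster annotation
  breaks toward the larger transcriptome cluster then lexicographic.
- Out-of-bounds fragments are dropped with a warning by default;
  `strict=True` raises. Malformed lines raise naming the 1-based line
  number.
- All randomness flows from a single seed through spawned
  `numpy.random.Generator` streams; identical config + seed reproduces
  every artifact hash.

## Problem sizes

The shipped defaults (840 cells, ~2M fragments per mark, 240 cCREs,
~850 candidate pairs, 10 shuffles) run the full pipeline in roughly
20–25 s on one CPU; the bundled test suite and the reproduction script
each finish in a few minutes. These sizes were chosen as the smallest
at which every stage's statistical behavior (FRiP calibration, peak
recovery, null calibration, link recovery) is stably measurable.

## Known limitations

- The co-occupancy score is a metacell correlation, not a
  graphical-lasso co-accessibility estimate; only its 0.1 threshold is
  shared with common practice.
- The doublet heuristic has ceiling recall ≈ 0.55 at factor 2 under
  additive doublets (see above); it exists to exercise the removal
  plumbing, not to compete with dedicated doublet callers.
- Repressive-mark clustering is intrinsically harder than active-mark
  clustering here: the reflection compresses relative contrast among
  high-signal elements, and type-uniform elements carry no signal, so
  its ARI can dip below the active mark's on some seeds — consistent
  with repressive marks resolving fewer clusters than transcriptomes.
- `run_pipeline` drives the synthetic workflow; file-driven analyses
  compose the same stages through the CLI stage commands or the
  library.
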