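# Methods

This note documents the models and procedures implemented in `keranet`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## The analysis problem

Keratinocytes progress from a proliferation-competent basal state (BK)
through a mitotic transition to terminal differentiation (DK). The pipeline
reconstructs this progression from single-cell RNA-seq, couples the turnover
of keratinocyte-specific transcription factors (TFs) to differential motif
enrichment in state-specific super-enhancers (SEs), infers module-level
TF→gene regulatory networks per state, and ranks TFs by a
differentiation-promoting score. Because the study-scale inputs (controlled
access single-cell data, a motif database, culture RNA-seq) are not
redistributable, the package ships a synthetic-data generator that produces
all inputs with the statistical structure the analysis assumes plus complete
planted truth; every claim the test suite makes is a claim about recovery of
that planted structure.

## Cell staging

* **Normalization.** `log2(1e6·c/colsum + 1)` per cell; a zero-count cell is
  a hard error naming the cell.
* **Embedding.** PCA (30 components, exact SVD) of log-cpm. The
  low-dimensional embedding is pluggable; PCA keeps the package
  self-contained where the original analysis used a zero-inflated
  factorization purely as a bias-corrected representation feeding distances.
* **Diffusion operator.** Affinity `a(i,j) = exp(−(d(i,j)/σ_i)²)` for `j`
  among the `k = 30` nearest neighbors of `i` (self included, affinity 1),
  with adaptive bandwidth `σ_i` = distance to the `ka = 10`-th neighbor;
  symmetrized `(A + Aᵀ)/2` and row-normalized. Duplicate points with
  `σ_i = 0` fall back to the global median positive neighbor distance.
* **Imputation.** `X·(Mᵀ)ᵗ` with `t = 6` for the first pass. `t = 0` is the
  identity by construction.
* **Clustering.** k-means-based approximate spectral clustering: m = 1,000
  k-means representatives (m = n skips the representative step and reduces
  to plain normalized spectral clustering); Gaussian affinity among centers
  with bandwidth = median pairwise center distance and zero diagonal;
  row-normalized top-K eigenvectors of `D^{-1/2}AD^{-1/2}`; k-means into
  K = 8; cells inherit their center's label. m = 1,000 matters: coarser
  representative sets merge adjacent stages. A disconnected center graph is
  clustered per connected component (K split proportionally) with a warning.
* **Stage order and orientation.** Labels are numbered 1..K along the first
  principal axis of the embedding, which fixes the sequence but not its
  direction. The pipeline orients the axis with the
  undifferentiated-culture FPKM table: TFs robustly expressed in
  proliferating culture must peak early; if their FPKM-weighted mean peak
  stage falls in the upper half, all labels flip (`s → K+1−s`). Without an
  anchor the direction is a coin flip of the SVD sign.
* **Outlier removal.** Within each stage, cells whose distance to the stage
  centroid strictly exceeds `median + 3·MAD` (raw MAD) are dropped; stages
  smaller than 5 cells are skipped with a warning; removing more than half a
  stage is an error. With MAD = 0 nothing is removed (strict inequality).
* **Re-imputation.** After outlier removal the operator is rebuilt
  deliberately lighter — `k = 10`, `ka = 4`, `t = 1` — and cpm re-imputed.
  This reduction is essential, not cosmetic: heavy smoothing drives every
  pair of stage-dynamic genes toward the correlation of their stage-mean
  profiles, which inflates false positives in all downstream correlation
  analysis (TF targets, module edges). The light pass removes most
  measurement noise while keeping the cell-level TF activity signal that
  identifies true targets.
* **Stage profiles.** `mean_expr(g,s) = log2(mean imputed cpm + 1)`;
  `normalized` is the per-gene z-score across stages (population SD;
  min-max available). Numerically constant rows map to zeros and are
  flagged rather than propagating NaNs.
* Genes and cells are processed in lexicographic identifier order, making
  all outputs invariant to input row/column order.

## Specificity screen, gene sets and differential expression

* **Screen.** TSS-level features are summed onto genes; each gene gets a
  two-sided Mann–Whitney U of the keratinocyte samples (3 by default)
  against the remaining samples, BH across genes; selection requires
  q < 0.05 *and* a higher target-group mean. A config list of excluded
  sample ids generalizes the exclusion of a non-epidermal replicate.
* **Expression filters.** Screen survivors must show ≥ 1 UMI in ≥ 1% of
  cells (ceil); DE uses genes with ≥ 3 UMIs in ≥ 20 cells, united with the
  keratinocyte gene set.
* **Gene sets.** `keratinocyte_tfs = screen_tfs ∪ curated_tfs`,
  `candidate_tfs = screen_tfs − curated_tfs`,
  `keratinocyte_genes = keratinocyte_tfs ∪ screen_genes`; manual additions
  are appended to the screen TFs with provenance retained. A TF annotation
  list splits TFs from other genes.
* **Mann–Whitney policy.** Exact enumeration when the pooled sample size is
  ≤ 12 and tie-free, else the normal approximation with tie and continuity
  corrections (scipy backend). The fixed switch keeps results
  bit-reproducible; all-identical inputs return p = 1 with a warning.
* **Moderated DE.** For the two-group design: `logfc = mean(DK) − mean(BK)`
  of log2(cpm+1); residual variance `s²_g` on `d_g = n−2` df; the prior
  `(d₀, s₀²)` is moment-matched from the distribution of `log s²_g` via the
  digamma/trigamma identities, with `s₀²` following a lowess trend in mean
  log-expression when `trend=True` (smoother choice is free; lowess with
  frac 0.5 is used); posterior `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)`;
  `t_mod` on `d₀+d_g` df; BH across genes; state-specific = q < 0.05 and
  |logfc| > 0.25. A near-constant variance distribution (non-positive
  moment estimate) yields `d₀ = ∞`, i.e. the pooled prior, with a warning —
  in that regime `t_mod` legitimately differs from the per-gene t by the
  latter's own variance noise (~0.1 at the tail of 200 genes), which is why
  the equivalence test bounds the median, not the max, tightly. `logfc` is
  the plain group-mean difference, which is limma's coefficient for a
  two-group design.

## Trajectory clustering and the antioxidant analysis

Genes pass a dynamic filter (stage-wise log2 range ≥ 1 by default, over
stages 1..K−1 — the differentiation trajectory, excluding the off-trajectory
stage 8), and are clustered agglomeratively (average linkage) on
`1 − Pearson` between stage-mean trajectories. Items are sorted
lexicographically before linkage, making the tree order-invariant. The
two-branch cut of the keratinocyte TFs defines the BK branch (lower mean
peak stage) and DK branch. For the antioxidant gene list, a three-cluster
cut is tested for the size of its largest cluster against an
equal-probability exact binomial null `P(X ≥ k | n, 1/n_clusters)` computed
by direct rational summation. The equal-probability null is a package
choice (the original's null is unstated); the package does not claim to
reproduce any published p-value for this analysis. A generic hypergeometric
set-enrichment utility (BH-corrected, GMT input) covers functional
annotation of modules and clusters.

## Super-enhancer motif enrichment

* **Scanning.** Log2-odds PWM (background-weighted pseudocount 0.5, uniform
  background by default), integer-rounded at scale 1000; the hit threshold
  is the smallest integer score whose exact null tail probability (DP
  convolution over positions under the background) is ≤ the scan p-value
  (default 1e-4). Both strands are scanned (reverse strand = reverse
  complement of the matrix), overlapping hits all count, `N` contributes 0.
* **Differential enrichment.** Per-kb counts per region; two-sided
  Mann–Whitney U (shared implementation) between BK and DK regions per TF;
  BH across all scanned TFs; direction assigned only at q < alpha; signed
  magnitude = rank-biserial `2·AUC(BK over DK) − 1`, chosen because it is
  the effect size canonically attached to the U test, bounded and
  sign-symmetric (the original's magnitude definition is unavailable).
* **Concordance.** One-sided Mann–Whitney U that BK-branch TFs have larger
  signed magnitudes than DK-branch TFs, by default restricted to TFs with a
  significant direction.

## Module-level regulatory networks

Per state: cells restricted to stages 1–4 (BK) or 4–7 (DK, both sharing the
mitotic transition stage); TFs restricted to those with motifs enriched in
that state's SEs; candidate genes = keratinocyte genes minus the genes
specific to the *other* state ("not down-regulated" in the network's
state). Similarity `S_ij = sign(r)·|r|^β` with β = 6 (the conventional
signed-coexpression power) over log2(re-imputed cpm + 1). TF modules:
agglomerative 1 − Pearson on per-cell TF expression. Gene modules:
agglomerative 1 − Pearson between the genes' rows of S (their
TF-correlation profiles); constant rows are assigned post hoc to the
nearest module centroid (Euclidean) and flagged. Edges: for every module
pair, `mean_s = mean_{i∈A,j∈B} S_ij`; an edge exists iff `|mean_s|` exceeds
the threshold, signed by the mean. The default threshold is the 95th
percentile of a gene-label permutation null (200 permutations, pooled over
module pairs) — a null-calibrated default standing in for the original's
unpublished fixed threshold; both module counts and the threshold are
config. Default module counts cap at 13 TF / 23 gene modules (BK) and
9 / 21 (DK), treated as data-dependent settings, not outcomes to reproduce.

## TF prioritization

Candidate TFs (screen TFs not in the curated list) get targets = genes with
`|Pearson r| ≥ 0.3` against the TF over re-imputed log expression across
trajectory-stage cells (raw correlation, not soft-thresholded, so the score
keeps interpretable units); score = `Σ sign(r_t)·logfc_t` with `logfc` from
the moderated DE (DK − BK). Strongly negative = basal-promoting. TFs with
culture expression < 5 FPKM are excluded (exactly 5 is retained); the
remainder is ranked ascending by score with deterministic tie-breaks
(target count, then id). Every score is reconstructible from the stored
per-target audit list.

## The synthetic cohort

Defaults are the study conditions the pipeline is exercised at: 3,000 cells
× 1,500 genes, K = 8 stages (BK = 1–3, mitotic = 4, DK = 5–7, plus an
off-trajectory stage 8), 10 TFs (5 basal-peaking, 5
differentiation-peaking) with 20 signed targets each, 200
keratinocyte-specific but stage-flat genes, 32 antioxidant genes in three
coherent trajectory classes (20 basal / 6 mid / 6 late), a 495-sample bulk
atlas with a 3-sample keratinocyte group (+4 log2 planted effect, split
over 1–3 TSS features per gene), and 50 SEs per state (1–3 kb, GC 0.41)
with consensus motif sites planted as Poisson processes at 1/kb (×3 in the
enriched state; 8-bp consensus PWMs of ~10.3 bits).

Generative model per cell: each gene has a smooth unimodal log2 stage
profile; each TF's *activity* is its profile value plus large cell-level
noise (SD 1.5) — single-cell TF expression is dominated by cell-to-cell
variability — and targets are coupled to the standardized activity with
weight 2.0 log2 units per SD plus residual noise (SD 0.5). Background
genes additionally carry independent per-stage level shifts (SD 0.6): most
of the transcriptome changes between differentiation stages, and these
"fingerprints" are what makes the K stages discrete expression states
rather than a continuum. Counts are negative binomial (dispersion 0.1)
around `library_size · relative expression` with a constant expected
library size of 5,000 UMIs, then zeroed independently with probability 0.3
(dropout). All randomness flows from one root seed through named
substreams; identical (config, seed) reproduce byte-identical outputs.

Two of these choices deserve emphasis because the recovery properties
depend on them: without stage fingerprints the stages are unclusterable in
principle (the trajectory is a continuum), and without dominant cell-level
TF activity noise any imputation drives all TF pairs toward their (mutually
similar) stage-profile correlations, destroying the identifiability of
TF-specific modules. Both are defensible features of real data, but they
mean that passing recovery tests demonstrates correctness of the machinery
under these conditions — not performance on real tissue, where stage
discreteness, TF noise structure, batch effects, doublets and ambient RNA
(all unmodelled) differ.

`target_lfc` in the planted truth is the model-implied expected DK − BK
difference of log2(cpm+1), including the `(1 − dropout)` attenuation that
independent zeroing imposes on any log-scale group difference; the
moderated-DE bias test is run at a larger library size (30,000) where the
remaining Jensen-type bias of log-of-counts is level-independent and
cancels between states.

## Numerical and degenerate-input conventions

Zero-variance vectors are errors at correlation operations (callers
pre-filter) except where a documented fallback exists (gene-module
Euclidean fallback, z-score zero rows). Constant rows are detected with a
relative tolerance of 1e-10. Ties: nearest-representative assignment takes
the lowest index; peak stages take the lowest stage and set a tie flag;
ranking ties break by target count then id. The exact/approximate
Mann–Whitney switch is fixed (≤ 12, tie-free) for bit-reproducibility.
Permutation thresholds use ≥ 100 permutations by construction.

## Problem sizes used in tests and the acceptance script

Unit tests run on reduced cohorts (hundreds of cells); the acceptance
experiments use the full default cohort for recovery, a 40-motif null panel
for the enrichment false-positive rate, 100 scoring replicates at 400 cells
× 300 genes for the ranking property, 10,000 null draws for the rank-test
calibration and ten 2,000-gene null matrices for the DE calibration —
sizes chosen so the whole suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the tested margins.

## Known limitations

* The staging method's accuracy degrades on much smaller cohorts (fewer
  fingerprint genes); the defaults are tuned to the default cohort scale.
* The module-edge truth metric is defined at module resolution; it does not
  validate single TF→gene edges (explicitly out of scope).
* The concordance and cluster-size analyses use the package's own null
  choices where the original's are unstated; config exposes alternatives.
* Real-data idiosyncrasies (batch, doublets, ambient RNA, UMI saturation)
  are not modelled, by design.
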