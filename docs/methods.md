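# Methods

This note documents the models and procedures spotmosaic implements, the
parameters that matter, what the synthetic data emulate (and do not), and
the numerical choices made where the design was genuinely open.

## Stitching multiple capture areas

A tissue section wider than one 6.5 mm capture array is profiled on
several overlapping arrays. Alignment starts from a coarse affine
transform per array (in practice exported from manual image alignment; the
identity for synthetic data) and is refined from ≥ 4 matched landmark
points per overlapping pair:

- **Rotation**: every unordered pair of landmarks defines a segment in
  each array; the signed angle between the two segments (atan2 of cross
  over dot) enters a weighted *circular* mean with weight √(ℓ_A·ℓ_B), the
  geometric mean of the segment lengths. The circular mean (resultant of
  weighted unit vectors) avoids ±π wrap-around and reduces to the
  arithmetic mean for small angles. Zero-length segments are skipped with
  a warning; all-zero input is a degenerate-input error.
- **Translation**: the second array's landmarks are de-rotated about their
  centroid and the translation is the mean of the per-landmark residual
  vectors. The rotation pivot is unidentifiable on its own; fixing it at
  the landmark centroid only re-parameterizes the translation, which is
  then solved consistently.
- **Propagation**: arrays form a graph with landmark-sharing pairs as
  edges; the graph must be connected (the error names the components).
  The first array (sorted by id) is held fixed and pairwise refinements
  are composed along a BFS spanning tree.

On noiseless synthetic pairs this recovers planted transforms to < 1e-9 px;
with σ = 2 px landmark jitter and 8 landmarks the estimate stays within 1°
and 3 px of the least-squares rigid (Kabsch) solution — the two estimators
are not identical (the weighted angle mean is not the SVD optimum) but
agree closely at realistic noise.

**Artificial grid.** After stitching, per-array coordinates are replaced
by one donor-level hexagonal lattice: pitch = the first array's median
nearest-neighbour spacing (the pixel realization of 100 µm), origin at the
minimum pixel coordinates (array indices 0), rows/columns extended to
cover every spot. Column indices advance in half-steps with column parity
equal to row parity, the native Visium convention, so lattice
nearest-neighbour distance is exactly one pitch. Each spot takes the array
coordinates of its nearest lattice point; exact ties go to the
lexicographically smallest (row, col), and spots from different arrays may
legitimately share coordinates in overlap regions.

**Overlaps.** A spot overlaps another array when its nearest cross-array
spot lies within 1.5× the native median nearest-neighbour distance; each
spot is paired with that nearest counterpart only (pairing every spot
within the threshold would link a spot to its counterpart's entire first
neighbour ring). Per overlapping array pair, the side whose overlapping
spots have the lower minimum UMI count is flagged for exclusion; ties
flag the later-listed array.

**Edge distance** is the distance from a spot's *native* array
coordinates to the boundary of the native rectangle [0, 77] × [0, 127]
(min of the four edge distances), used in the QC conjunction below.

## QC and normalization

A spot is excluded iff UMI < 250 **and** edge distance < 6 — a
conjunction, because depth is systematically lower in white matter and a
global depth cutoff would delete real tissue; only shallow spots at the
array margin are treated as artifacts. MAD filters operate per batch
(e.g. sorting paradigm) with per-batch multipliers, the 1.4826 consistency
constant, optional log1p scale for library sizes, and lower-tail-only
direction by default (low quality = low depth); zero-MAD batches flag
nothing. Mitochondrial fraction is filtered strictly above 0.05 and
doublet scores at ≥ 5 (inclusive). Normalization offers
`ln(c/L·10⁴ + 1)` (scale-factor) and `log2(c/sf + 1)` with
sf = L/mean(L) (size-factor); zero-library observations are dropped with
a warning. Cross-donor aggregation of spatially-variable-gene rankings
keeps genes significant in every donor (padj < 0.05), averages ranks,
re-ranks (ties alphabetical) and returns the top 2,000.

## Spatial patterns

The spatial graph is binary: W_ij = 1 iff 0 < d(i,j) ≤ threshold, no row
standardization, S₀ = ΣW. On a hexagonal lattice a threshold of 1.5×pitch
captures exactly the six first-ring neighbours (the second ring is at
√3×pitch). Statistics:

- Moran's I = (n/S₀)·Σ W_ij z_i z_j / Σ z_i², permutation p-values
  optional (E[I] under permutation is −1/(n−1)).
- Local Moran I_i = (z_i/m₂)·Σ_j W_ij z_j with m₂ = Σz²/n. Significance
  uses conditional randomization: spot i's value is held fixed, its
  neighbours' values are draws without replacement from the other n − 1.
  The default p-value is **analytic** — the conditional mean
  −z_i²·w_i/(m₂(n−1))-form and the exact without-replacement variance of
  the lag feed a normal reference — and **one-sided (greater)**: a spot
  "contributes to a pattern" through positive local association
  (high-high or low-low). Conditional permutation is available
  (`method="permutation"`), but with n_perm permutations its p-values are
  floored at 1/(n_perm+1); after BH correction across ~10³ spots that
  floor makes the 5 %-of-spots rule discontinuous (whole genes flip
  between fraction 0 and 0.15 on negligible signal changes), which is why
  the continuous analytic form is the default. A gene passes the filter
  when ≥ 5 % of spots reach FDR < 0.05.
- SCC(a,b) = (n/S₀)·Σ W_ij za_i zb_j / √(Σza²·Σzb²), symmetrized as
  (M+Mᵀ)/2, so SCC(a,a) collapses to Moran's I of a (asserted in tests).
  Zero-variance genes get zero rows with a warning.
- Genes are grouped by hierarchical clustering on 1 − SCC (complete or
  Ward linkage; cut by k or height); pattern scores are the mean z-scored
  expression of member genes per spot.

Interpolation of scores into unmeasured regions is a display device and is
not implemented.

## Cross-donor consensus patterns

For patterns detected independently per donor, two similarities are
computed: the Jaccard index of member gene sets (two empty sets define 0)
and the Pearson correlation of domain-mean score profiles (≥ 3 shared
domain labels; zero-variance profiles correlate 0). The consensus
similarity is their plain mean — a [0,1] quantity averaged with a [−1,1]
one, implemented as printed with the caveat exposed; negative entries are
floored at 0 only when converting to the Ward distance 1 − sim (Ward needs
a valid dissimilarity; scipy's linkage is the ward.D2-style update). The
tree is cut at a configurable k (default 6). Within each consensus group a
donor contributes its single pattern as representative; donors
contributing several contribute none unless the highest-mean-score
override is requested. Clusters lacking multi-donor support can be dropped
by the caller; no automatic discard criterion is imposed.

## Registration

Pseudobulk counts are summed per (group, unit); samples with < 50
contributing observations, samples detecting < 2,000 genes, and groups
with < 10 samples are dropped (all configurable — the synthetic fixtures
scale these down). The one-vs-all statistic is

    t_{g,c} = (X̄_{g,c} − X̄_{g,−c}) / √((σ²_{g,c} + σ²_{g,−c}) / (2 n_c))

with n_c the group's own size — deliberately *not* Welch's statistic (the
complement's size never enters the denominator); a Welch variant with
Satterthwaite df sits behind `welch=True`. p-values use a t reference with
2n_c − 2 df (needed only for the marker filter; the statistic itself is
consumed as a correlation profile), BH-corrected per group. Markers are
FDR < 0.05, logFC > 0, top 250 by logFC. Cross-species lists pass through
strict one-to-one homolog pairs (any symbol in more than one pair is
dropped). Registration correlates query and reference t-profiles over
either an explicit marker union or the union of each reference group's
top-100 t genes; a universe under 3 genes is an error.
Over-representation builds the 2×2 list × DEG-set table over a declared
universe, reports the sample odds ratio ad/bc and the one-sided Fisher
exact p (verified against hypergeometric tail enumeration for all tables
N ≤ 30), and skips lists under 25 genes as under-powered. Heritability
gene sets take the top ceil(n·fraction) genes by within-group relative
expression (CPM over summed CPM), extend each gene's span ±100 kb
strand-agnostically, clip at zero, drop chrX/chrY/chrMT, and emit sorted
0-based half-open BED (gene coordinates are declared 1-based inclusive and
converted on read).

## Factor models

NMF minimizes 0.5‖M∘(A − WH)‖² + l1·‖W‖₁ by multiplicative updates (the
L1 term enters the W-update denominator), with an optional observation
mask M. The objective trace is recorded and is non-increasing — asserted
in the tests with a 1e-8 relative tolerance for floating-point slack.
Defaults: l1 = 0.1 on W only, tol = 1e-6 relative objective change,
maxit = 1000, uniform random init scaled to the data (seeded). After
convergence each factor is rescaled so its W column sums to one, the scale
absorbed into H. Rank selection masks a random 20 % of entries per
replicate *out of the objective* (not zero-filled, which would bias toward
sparse reconstructions), scores held-out RMSE, and recommends the smallest
rank within one standard error of the minimum. Transfer uses the literal
projection H′ = WᵀA′ over the gene intersection (model order), with a
non-negative least-squares mode as an alternative, then normalizes each
spot's factor vector to sum to one (all-zero spots exempt and flagged).
Screening drops factors with |r| > 0.3 against the sex indicator or
nonzero projections in < 200 spots; per-domain summaries report prevalence
(fraction of nonzero projections) and the mean projection z-scaled across
domains within each factor (association = prevalence > 0.2 and scaled
mean > 0.2 in ≥ 1 domain; the scaling axis across domains is this
package's reading). The condition screen is a two-sided Wilcoxon rank-sum
per (factor, cell type) with rank-biserial effect r = 2U₁/(n₁n₀) − 1
(+1 at complete separation), BH across all tests, responsive = |r| > 0.3
and FDR < 0.05 in ≥ 1 cell type.

## Ligand–receptor co-occurrence

Candidates keep only pairs where ligand or receptor has maximum trait
evidence > 0.1 ("no data" = 0), neither symbol starts with "HLA", and the
aggregate rank is ≤ 0.01. A spot expresses a gene when its log-normalized
value is > 0, giving the four-way classification. With deconvolution
weights W (rows renormalized to sum to one unless disabled), the
co-occurrence over a spot set S is C = W_Sᵀ W_S with the diagonal and
strict upper triangle zeroed and the lower triangle normalized to sum to
one; the enrichment ratio is R = C_LR/(C_ctrl + 1e-6), the ε added to the
control matrix only, exactly as the statistic is defined. An empty
co-expressing (or control) set flags the result undefined rather than
erroring. QC-excluded spots should be removed before classification so
they enter neither spot set.

## Model-selection metrics

BIC = −2·LL + df·ln(n) (natural log). The degrees-of-freedom accounting of
the upstream spatial clustering tool is not recoverable from its outputs,
so `default_df` (p·q loadings + k·q means + covariance parameters
[k·q diagonal / q shared / k·q(q+1)/2 full] + r_max) is explicitly
pluggable and a caller-supplied df wins. The Rand index is the plain
(unadjusted) fraction of agreeing pairs; overlap concordance is the
fraction of overlapping spot pairs sharing a cluster label and is an error
with no pairs.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (config, seed). Capture areas are
windows of one global hexagonal lattice, so cross-array overlap spots are
exactly coincident; landmark pairs get Gaussian jitter of configurable σ.
Counts are negative binomial with variance µ + µ²/θ; defaults are
per-gene mean 2.5 and θ = 5 with 8-fold marker enrichment, so the default
120-gene panel yields ≈ 300 UMIs per spot — comfortably above the 250-UMI
floor the QC rule presumes for real tissue spots. Domain layouts are a
lateral gradient (marker means ramp linearly along x), circular islands,
or uniform. Nuclei carry disjoint cell-type markers plus a small
sex-linked program (to exercise the sex-correlation exclusion) and a drug
program shifted in selected cell types (to exercise the condition screen).
Deconvolution weights are Dirichlet draws centred on per-domain mixtures;
factor data are exact non-negative products W·H with optional truncated
noise; ligand–receptor weights up-weight a planted cell-type pair in
co-expressing spots.

The synthetic data deliberately omit: realistic transcriptome-scale gene
panels and library-size variation, spatial autocorrelation of technical
noise, segmentation/imaging artifacts, batch and donor covariance
structure, and any gene-length or GC structure. Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
stated noise model, not performance on real tissue.

## Problem sizes and determinism

Test and example runs use 15×15–50×50 lattices, 40–200 genes, and
400–1,800 nuclei — sizes chosen so every planted effect is recoverable
with comfortable margins while the whole suite runs in well under a
minute. All randomness flows through numpy Generators seeded explicitly;
the pipeline fans one global seed out per stage by stable hashing of the
stage name, and a rerun with identical configuration is byte-identical.

## Known limitations

- The weighted-angle rotation estimator is not the least-squares optimum;
  it matches Kabsch only approximately under noise (within 1°/3 px at the
  tested conditions) and degrades if landmarks are nearly collinear.
- H′ = WᵀA′ is a faithful implementation of the stated projection but is
  not a least-squares fit unless W has orthonormal columns; the `lstsq`
  mode exists for when the reconstruction interpretation matters.
- The min-count/min-proportion gene filter approximates, not reproduces,
  the pseudobulk expression-filter heuristic of the edgeR ecosystem.
- Multiplicative NMF updates converge slowly near the optimum; for exact
  reconstruction demands, raise `maxit` and lower `tol` (the noiseless
  recovery test uses maxit = 2000, tol = 1e-10, l1 = 0).
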