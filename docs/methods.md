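# Methods

`msifilter` removes peaks with implausible spatial distributions from
peak-matched mass spectrometry imaging (MSI) datasets.  The input is a
pixel × peak intensity matrix on a 2-D raster with one m/z value per column;
the output is the same dataset restricted to the peaks that survive a
configurable sequence of spatial filters.  This note records the models,
the free parameters and the design choices behind each component.

## Data model and conventions

Pixels are stored in row-major grid order, 0-based; imzML 1-based x/y
coordinates map as `col = x − 1`, `row = y − 1`.  Grid cells without a
recorded spectrum are zero-filled with a warning — the filters require a
complete raster.  Intensities are filtered as delivered by upstream peak
matching; no normalisation is applied by default (whether intensities
should be TIC-scaled first is left to the caller, since the similarity and
CSR statistics are invariant to a global per-peak scale anyway, and
per-pixel scaling would change the TIC covariate itself).

**Otsu threshold.**  All binarisations use the same primitive: the
histogram threshold maximising between-class variance, searched
exhaustively over the interior edges of 256 equal-width bins spanning
[min, max]; class statistics are computed from the actual pixel values on
either side of the candidate edge, and ties resolve to the lowest edge.
"Signal" is strictly greater than the threshold, which keeps an exactly-zero
background out of the signal class.

**Connectivity.**  Connected components and neighbourhood tests use
8-connectivity by default (diagonal contacts count); every operation that
labels pixels accepts `connectivity=4`.

## Spatial regularity measures

Three measures score how structured one ion image is; all are reported
oriented so that 1 = regular/localised:

- **Scatter ratio** — fraction of Otsu signal pixels outside the largest
  connected component; oriented value is its complement.  "Disconnected
  signal pixels" is deliberately defined against the largest component:
  this makes the score monotone in fragmentation and bounded in [0, 1].
- **Spatial chaos** — for 64 thresholds on the quantile grid of the nonzero
  intensities, binarise (a pixel is signal when its value reaches the
  level) and record the fraction of signal pixels with no signal neighbour;
  chaos is the mean over levels that retain signal.  This is a variant
  construction (the edge-detection-based "measure of chaos" in the
  literature is underspecified); it is pluggable behind the same oriented
  interface.
- **Gini index** — concentration of the intensity distribution, computed
  with the sorted-value identity; 0 for a uniform image.  Note that Gini
  measures *intensity* concentration, not spatial contiguity: a scattered
  but sparse image also scores high, which is why it is not the default
  regularity measure for merging decisions.

## Similarity measures

Pearson and Spearman correlations act on flattened pixel vectors.  SSIM is
the mean local structural similarity with a Gaussian window (σ = 1.5) and
constants C1 = (0.01 L)², C2 = (0.03 L)², L the larger dynamic range of the
pair.  NMI is I(A;B)/√(H(A)·H(B)) on 256 equal-width bins (a binary mask
keeps its two natural levels); the geometric-mean normalisation is
symmetric and bounded in [0, 1].  A constant image has no defined
correlation or entropy: the metric layer raises, and the filters translate
that into a −∞ score, i.e. a constant ion image always fails — it carries
no spatial information.

## Split-peak merging

Upstream peak matching can split one ion across contiguous m/z bins within
the instrumental error.  Candidates are transitive chains of adjacent peaks
with gaps ≤ `tol_ppm` (default 10 ppm; the tolerance is the instrument's
mass-accuracy specification and an absolute-Da variant can be emulated by
converting at the relevant mass).  A candidate group is merged iff

1. every pairwise overlap |A∩B|/min(|A|,|B|) of the members' Otsu signal
   masks is ≤ `overlap_max` (default 0.5 — "small or non-overlapping" made
   operational; true split members partition one source and overlap ≈ 0);
2. the best member's oriented scatter regularity is ≥ `regularity_min`
   (default 0.05 — deliberately permissive, because a split member is a
   randomly decimated image whose regularity falls quickly with the number
   of components, while shot-noise images stay below ≈ 0.04: their largest
   component holds a few per cent of the signal pixels);
3. the merged (pixel-wise summed) image is at least as regular as the best
   member, up to `regularity_slack` (default 0.05).  The slack absorbs
   binarisation noise: when a 2-way split member nearly percolates, its
   regularity estimate can exceed the merged image's by a few hundredths
   even though merging is clearly correct.  Set the slack to 0 for the
   strict comparison.

Merging sums intensities pixel-wise (conserving total ion count exactly)
and assigns the intensity-weighted mean m/z of the members.  The tool
iterates to a fixed point (≤ 3 passes) because a merged peak can re-chain
with its neighbours.  Merging must precede the other filters, which score
exactly the spatial structure that splitting destroys.

## Reference similarity filter

Each peak's ion image is scored against a reference — the binary tissue ROI
or a per-pixel summary (sum/mean/median/first-PC scores, the last sign-fixed
against the TIC) — and kept when the score is strictly above the threshold
(default 0).  The strict inequality at 0 keeps weakly-positively-correlated
ions that occupy small sub-regions of the tissue while dropping exact-zero
and negative scores.  The ROI comes from Otsu-thresholding a reference
image or from 2-means clustering of the pixel intensity vectors (seed 0,
10 restarts, ROI = cluster with larger mean TIC); external pre-registered
rasters are accepted as-is (registration is out of scope).

## Connected-pixel-count filter

Per peak: Otsu-binarise, label components, keep the peak when a component
has at least `min_pixels` pixels *inside* the ROI (ROI-restricted size; a
flag switches to total size of ROI-intersecting components).
Aggressiveness levels nest — level 1 additionally requires the largest
ROI-restricted component to be at least as large as the largest fully
outside component, level 2 requires more signal pixels inside the ROI than
outside — so keep-sets shrink with the level, and under an all-ones ROI all
levels coincide.  `min_pixels` encodes the smallest meaningful anatomical
sub-region at the acquisition's pixel pitch (default 4).

## Complete-spatial-randomness filter

Otsu signal pixels define a point pattern in the grid rectangle.

**Clark–Evans**: R = mean observed NN distance over 1/(2√λ), λ = n/area;
z uses SE = 0.26136/√(nλ) and the default alternative is one-sided towards
aggregation (informative ions cluster).  Without edge correction the raw
test is conservative towards aggregation — border points inflate the mean
NN distance (for n = 100 on a 64×64 window the bias is ≈ +0.85 SE, pushing
the one-sided type-I error below 0.01) — so `correction="toroidal"`
(exactly calibrated under CSR) and `correction="donnelly"` (rectangular
edge adjustment) are provided; the calibration checks run the toroidal
variant.  A further caveat specific to binarised images: dense pixel masks
have NN distances quantised to the grid spacing, which looks *regular*
(R > 1), so the aggregation-sided test has power only for sparse masks.
The covariate-KS test below is the workhorse for dense signal.

**Covariate KS**: under CSR the covariate values observed at the pattern
points are a uniform draw from the covariate values over all window pixels,
so D = sup|F̂_points − F_window| (both CDFs right-continuous, the supremum
evaluated at every distinct covariate value).  The p-value uses the
asymptotic Kolmogorov distribution with effective sample size
n_eff = n/(1 − n/N): the points are a without-replacement sample of the N
window pixels, which shrinks the null fluctuations of D by √(1 − n/N); the
plain √n scaling (available via `finite_population=False`) is mis-calibrated
once the pattern covers a non-trivial fraction of the window.  When the
covariate is a sum-type image (TIC) that contains the tested peak, the
pipeline subtracts the peak's own column first (`exclude_self`): the
self-contribution makes the covariate pattern-dependent under the null and
biases the test towards rejection — negligible for thousand-peak datasets,
material for small ones.

p-values are adjusted across the full peak set (Bonferroni by default,
Benjamini–Hochberg optional; degenerate peaks count towards m,
conservatively) and a peak is kept when its adjusted p is below α
(default 0.001).

## Pipeline

Stages run in order, each consuming the survivors of the previous one;
split-merge, when configured, is always first.  The ROI and TIC covariate
are computed once on the dataset entering the filter stages.  The default
profile `maldi-default` is: Spearman vs 2-means ROI at threshold 0 → count
filter with min_pixels 4 (level 0) → covariate-KS CSR with the TIC,
Bonferroni α = 0.001.  Reports (per-stage TSV, summary, optional PNG
gallery of the five dropped and five kept peaks with the largest mean
intensities) are byte-stable across runs at a fixed seed.

## Synthetic data generator

The generator emulates the signal classes the filters must separate on a
64×64 grid by default: a tissue-shaped ROI (thresholded smoothed Gaussian
field occupying 35–55% of the pixels), 20 structured peaks (smooth positive
fields on the ROI, additive N(0, 0.05) noise clipped at zero), 15
off-tissue peaks (same construction on the complement), 15 shot-noise peaks
(Bernoulli pixel processes at 5% density with U(0.5, 1) marks — the
pixel-grid analogue of a homogeneous Poisson process), and optionally
planted split groups (a structured image partitioned across 2–3 columns by
random pixel assignment at m/z offsets < 10 ppm; members sum exactly to the
source image).  The m/z axis is uniform on [500, 900] with ≥ 50 ppm
spacing outside split groups.  Everything derives from one seed.

What the generator does **not** emulate: isotope envelopes, mass-dependent
peak widths, correlated chemical noise, intensity heteroscedasticity,
detector saturation, or imperfect ROI boundaries.  Passing the recovery
tests therefore shows that the filters separate the four idealised signal
classes at realistic densities and noise levels — not that they are robust
to every artefact of real acquisitions.

## Problem sizes and numerical choices

Statistical checks use 64×64 grids with 50-peak datasets over 20 generator
seeds, 200-point/1000-replicate Clark–Evans nulls and 500-replicate KS
nulls — sizes at which every contract is measured with comfortable Monte
Carlo margins while a full run of suite plus acceptance script stays in the
tens of seconds.  Degenerate inputs are handled uniformly: constant images
cannot be thresholded or correlated and always fail the filter examining
them; empty merge plans and empty stage lists are identities; an exhausted
peak set stops the pipeline early with a warning rather than an error.

## Known limitations

- The spatial-chaos measure is a documented variant, not a reproduction of
  the edge-based construction it stands in for.
- Clark–Evans on dense binarised masks is insensitive to aggregation
  (grid-quantised NN distances); prefer the covariate-KS test there.
- External rasters must already be registered and sampled to the MSI grid.
- Aggressiveness levels of the count filter and the ROI-restricted
  component size are one reasonable formalisation of informally described
  behaviour; both have flags to switch conventions.
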