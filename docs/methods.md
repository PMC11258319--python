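# Methods

## Problem and model

A spatial omics slice is a set of `N` spots or cells with coordinates
`S ∈ ℝ^{N×D}` (`D` = 2 or 3, continuous platform units) and a non-negative
feature matrix `G ∈ ℝ^{N×F}` (gene counts, gene scores, protein
intensities, or a pre-computed joint embedding for cross-modality pairs).
Registration is restricted to **proper rigid motions** — rotation plus
translation, no scaling, shear or reflection — because serial sectioning
and remounting move tissue rigidly and cannot mirror it.  Non-rigid
distortion is out of scope.

### Coarse stage

All-pairs Pearson correlation between spot expression profiles (each
profile centred by its own mean across features) scores candidate
correspondences; every source spot takes its best-correlated target spot
(ties to the smallest index; matching is source→target only, so target
spots may be reused).  For partially overlapping slices the descending
correlation curve is segmented at the change point minimizing the summed
absolute deviation from each segment's median, with a minimum segment size
of 2 (a one-point segment has zero cost by construction, making the split
ill-posed); on an all-equal curve the largest admissible split is returned,
keeping the most pairs.  The rigid fit is the Kabsch/orthogonal-Procrustes
closed form on the surviving pairs; when the raw SVD solution has
determinant −1 the singular vector of the smallest singular value is
negated, giving the optimal *proper* rotation.  Degenerate pair
configurations (collinear in 2D, coplanar in 3D) raise an error rather than
returning an arbitrary rotation.

### Fine stage

Two edge-convolution networks (one over spatial coordinates, one over
omics features, weights shared between the two slices within each branch)
embed every spot's k-NN neighborhood.  Each layer maps the edge feature
`(x_i, x_j − x_i)` through a linear map plus leaky ReLU (slope 0.2) and
aggregates over neighbors with a channel-wise max; the k-NN graph is
recomputed in the current embedding space before every layer after the
first (dynamic update, applied to both branches); the final embedding
concatenates all layer outputs.  Defaults: `L = 3` layers, channels
(64, 64, 128), `k = 10`.  Omics inputs wider than 50 features are reduced
by joint PCA (both slices stacked, deterministic full SVD) so the graph and
network operate on a compact representation.

The correspondence map is the row softmax of the embedding similarity.
Two implementation choices here were left open by the stage's definition
and are ours:

- **Cosine similarity with a trainable sharpness.**  Raw dot products of an
  untrained network saturate the row softmax at initialization, freezing
  the map onto an arbitrary warp.  Each branch's embedding is row-
  normalized (so spatial and omics neighborhoods get equal influence) and
  the cosine similarity is multiplied by a trainable logit scale
  initialized at `1/sim_temp` (default 10).  At initialization the
  similarity of a random high-dimensional smooth feature map decays with
  distance, so the initial soft map respects the coarse placement.
- **Refinement acceptance guard.**  After training, the fine rigid
  transform is fitted from the coarse coordinates to the soft-mapped
  coordinates (identity pairing) and accepted only if it lowers the
  alignment objective evaluated at rigid configurations.  The soft map
  pulls points toward local target density (every row of the softmin sums
  to one, so diffuse maps shrink the cloud inward); this bias cannot
  affect a comparison *between rigid candidates*, making the objective a
  fair referee.  The guard removes the fine stage's rotational noise floor
  when the coarse placement is already converged and leaves genuine
  refinements untouched (verified: identical refinement errors with and
  without the guard on deliberately perturbed coarse stages).

The loss mixes expression dissimilarity and spatial distance under
distance-decayed (softmin) attention with weight `α` (default 0.3) and
temperature `τ` (default 1.0).  Coordinates are rescaled before training so
the median k-NN distance is 1 and the fitted transform is mapped back
afterwards, which makes one `τ` default meaningful across platforms whose
units differ by orders of magnitude.  The expression correlation matrix is
computed once (expression does not change during training); gradients flow
through the soft map and both networks.  Training uses Adam
(lr default 0.05, the midpoint of the 0.01/0.05/0.1 robustness grid;
epochs default 100).  All training runs on an in-package reverse-mode
automatic-differentiation engine over float64 numpy arrays
(`slicealign._autodiff`), whose gradients are pinned to central finite
differences in the test suite; float64 plus fully deterministic tie-breaks
(stable sorts everywhere) make runs bit-reproducible under a fixed seed.

### Serial stacking and 3D

`serial_stack` aligns slice `t` to the already-transformed slice `t−1`, so
each pairwise composed transform places the slice directly in the reference
frame; sections receive `z = t · z_spacing` (spacing is user-supplied,
default 1 unit — physical section spacing is platform metadata the package
cannot infer).  `align_3d_to_3d` runs the identical pipeline with 3×3
rotations, optionally after spatial binning (`bin_slice`, origin fixed at
coordinate 0, features summed per bin, majority label with lexicographic
ties) to bound memory; the transform estimated on binned clouds applies
unchanged to the originals.

### Downstream

Label transfer annotates each spot with the dominant cell-type among the
high-resolution cells within radius 30 platform units (the breast-cancer
setting; a flag), falling back to the 3 nearest cells when the circle is
empty; ties break lexicographically.  Gene imputation fits
`sklearn.linear_model.PoissonRegressor` (log link, L2 penalty 1e−6 for
numerical stability) of the untargeted gene — read off each overlap cell's
nearest spot — on the cell's panel features, and predicts mean rates for
cells outside the overlap.

### Metrics

PCC and CI use the spatially nearest target spot after alignment (distance
ties to the smallest index).  AAS is `360° − |Δangle|` in its literal form;
because that form is not wrap-aware (359° vs 1° scores 2, not 358), a
wrapped variant is available behind the `wrapped` flag.  `cluster_entropy`
is the natural-log Shannon entropy of each cluster's label counts; lower
entropy means a clearer anatomical structure.

## Synthetic data: what it emulates, and what it does not

The generator is the package's only data source for testing, so its
conditions define what the tests demonstrate.

- **Layouts.** `gaussian_blobs`: compact cell-type domains at random
  centres (σ = 12% of the tissue extent).  `layered_bands`: laminar strata
  perpendicular to the x axis, the axis along which stitching fixtures are
  clipped — the regime of sectioned layered tissue where the non-shared
  strip contains structures absent from the other slice.
- **Expression.**  Per-type mean programs (independent lognormal baselines
  plus 20× type markers) scaled so library sizes land in the low thousands,
  as in sequencing-based platforms; counts drawn Poisson or
  negative-binomial (gamma–Poisson, `var = μ + 0.5 μ²` by default, so
  correlation matching faces realistically over-dispersed counts).  On top,
  each gene carries a smooth log-linear spatial gradient (random direction,
  amplitude `spatial_gradient`, default 0.8 ≈ 2-fold across the tissue):
  real tissue expression varies continuously in space, and this is what
  gives a spot positional identity beyond its cell type.
- **Pairs.**  The source is manufactured from the same tissue by
  coordinate jitter, an exact rigid motion (the recorded truth), optional
  clipping, and by default an independent count draw from the same mean
  field (two assays of one tissue never share counting noise).
  `resample_expression=False` gives the clean condition: identical counts,
  so correlation matching is exact and geometric machinery can be tested in
  isolation.  For partial overlap both slices are clipped along x with the
  thresholds sized so the shared strip holds the requested fraction of each
  slice's spots.
- **Serial series.**  Random per-slice rotations up to 45° with small
  translations, monotone cell-type drift across z, and (in the clean
  condition) a count draw shared across sections.

What the generator does **not** emulate — and hence what passing tests do
not show: tissue morphology (boundaries, holes, anisotropic cell density),
platform-specific artifacts (spot swapping, segmentation errors, lateral
diffusion), batch effects between slices, and genuinely non-rigid
deformation.  Results on real sections with strong distortion will be
worse than the synthetic numbers.

### Identifiability of overlap detection

Change-point filtering of the correlation curve can only find the overlap
when the non-shared region expresses programs absent from the other slice.
If expression domains are broad relative to the non-shared strip, spots
just outside the overlap match same-domain spots inside it with
correlations indistinguishable from genuine overlap pairs; the measured
precision ceiling of *any* split of the correlation ranking is then far
below 1, an information limit of expression-based overlap detection rather
than an implementation property.  The stitching fixtures therefore use the
laminar layout with 40 bands across the tissue, where the limit does not
bind.  A second subtlety fixed during design: strong smooth gradients
*inflate* the profile correlation of edge spots with each other (both
profiles are dominated by the same extreme deviations after row centring),
which can rank non-overlap edge spots above interior overlap spots — the
laminar fixtures therefore keep the gradient amplitude modest (0.3).

## Problem sizes

Chosen once as the package's study conditions: rotation-grid recovery at
300 spots × 60 genes; stitching at 600 spots × 300 genes × 40 bands,
overlap 40/60/80%, 5 seeds; refinement of a 5°-perturbed coarse stage at
200 spots × 60 genes, coordinate noise 2% of slice width, negative-binomial
counts, median over 5 seeds; soft-map normalization on a 500-spot pair;
serial stacking of five 250-spot × 120-gene clean sections; imputation
recovery at 2000 training cells; label transfer on 600 cells / 200 spots.

## Numerical choices and degenerate inputs

Stable sorts with smallest-index tie-breaks everywhere (k-NN neighbors,
best-match ties, nearest-target queries, majority labels lexicographic);
softmax/softmin always max-shift stabilized; squared distances clamped at
zero before square roots; zero-variance expression rows get correlation 0
with a warning instead of NaN; all-zero library rows pass through
normalization unscaled with a warning; transforms serialize to JSON at 17
significant digits, which round-trips float64 exactly.

## Known limitations

The fine stage's objective is unsupervised and evaluated through a soft
map, so its rotational precision is bounded by spot density — at a few
hundred spots the per-pair noise floor is a fraction of a degree to a few
degrees (the acceptance guard, above, prevents this noise from degrading
already-converged placements).  Overlap detection carries the
identifiability limit described above.  Runtime of the fine stage grows
roughly quadratically with spot count through the all-pairs similarity and
distance matrices; very large slices should be binned first.
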