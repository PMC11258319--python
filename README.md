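# slicealign

Coarse-to-fine **rigid alignment and stitching of spatial omics slices** —
registering two or more tissue sections (spatial transcriptomics,
epigenomics or proteomics) into a common coordinate frame using only their
spot/cell coordinates and feature matrices, with no images or landmarks.

## Who this is for

Anyone with serial or replicate sections from platforms such as Visium,
MERFISH, Xenium, STARmap or Stereo-seq who needs to:

- **align** two (near-)fully overlapping slices,
- **stitch** partially overlapping slices, automatically detecting the
  shared region,
- **stack** a serial series into a 3D volume, or align two assembled 3D
  volumes (e.g. whole embryos from two developmental stages),
- run alignment-enabled downstream analyses: **label transfer** from a
  high-resolution slice onto spots, and **Poisson-regression imputation**
  of genes missing from a targeted panel.

## Method

**Coarse stage.** Each source spot `i` is matched to the target spot `j`
maximizing the Pearson correlation of their expression profiles across the
shared genes,

```
PCC(g_i, g_j) = Σ(g_i − ḡ_i)(g_j − ḡ_j) / √(Σ(g_i − ḡ_i)² Σ(g_j − ḡ_j)²).
```

For stitching, the matches are sorted by descending correlation and the
list is segmented by change-point detection — the split `x'` minimizing
`cost(left) + cost(right)` with `cost(I) = Σ_t |p_t − median(p_I)|` — and
only the left (high-correlation) segment, which concentrates in the
physically shared region, is kept.  The rigid transform is the closed-form
Kabsch/Procrustes solution: with cross-covariance `H = Σ (s_i − s̄)(d_i −
d̄)ᵀ` and SVD `H = UΣVᵀ`, the rotation is `R = VUᵀ` (reflection-corrected
so `det R = +1`) and `T = d̄ − R s̄`.

**Fine stage.** A dynamic-graph edge-convolution network embeds each
slice's spatial and omics k-NN neighborhoods (weights shared between the
two slices per branch); a row-stochastic soft correspondence map
`m = softmax(F_X F_Yᵀ)` pulls the source to `S″_X = m S_Y`; the
unsupervised loss

```
Loss = (1/N_X N_Y) Σ_i Σ_j softmin_ij [ α(1 − PCC_ij) + (1 − α) Dis_ij ],
softmin_ij = exp(−Dis_ij/τ) / Σ_j exp(−Dis_ij/τ)
```

is minimized by Adam, and a final rigid SVD fit from the coarse to the
soft-mapped coordinates gives the fine transform.  Training runs on a small
reverse-mode automatic-differentiation engine over numpy included in the
package (`slicealign._autodiff`), verified against finite differences.

**Metrics.** PCC (mean nearest-neighbor expression correlation), CI
(fraction of nearest-neighbor pairs sharing a cell-type label) and AAS
(`360° − |angle_pred − angle_gt|`).

## Worked example

```python
import slicealign as sa

# a synthetic pair: tissue rotated by 60 degrees, full overlap
spec = sa.SimulationSpec(n_spots=300, n_genes=60, rotation_deg=60.0,
                         translation=(8.0, -5.0), expression_model="poisson",
                         resample_expression=False, seed=21)
pair = sa.make_pair(spec)

result, pairs = sa.align_pair(pair.source, pair.target,
                              sa.PipelineConfig(mode="align"))
print("recovered rotation:", round(sa.rotation_angle(result.composed), 3))
print("ground truth:      ", round(sa.rotation_angle(pair.truth.inverse()), 3))

aligned = pair.source.with_coords(
    sa.apply_transform(result.composed, pair.source.coords))
xh, yh = sa.harmonize_features(aligned, pair.target)
print("CI after alignment:", sa.cell_type_matching_index(xh, yh))
```

Output:

```
recovered rotation: 300.0
ground truth:       300.0
CI after alignment: 1.0
```

The generator rotated the source by +60°, so the aligner must rotate it
back by −60° ≡ 300°; on this clean pair the correlation matching is exact,
the coarse SVD fit recovers the angle to machine precision (the fine stage
finds nothing left to improve), and every spot lands nearest a spot of its
own cell type.

The same pipeline is available from the shell:

```bash
slicealign simulate --n-spots 300 --rotation 60 --out fixtures/
slicealign align --source fixtures/source.h5ad --target fixtures/target.h5ad \
    --mode align --out run1/
slicealign metrics --aligned-source run1/aligned_source.h5ad \
    --target fixtures/target.h5ad --out run1/metrics.tsv
```

Inputs are h5ad (coordinates in `obsm["spatial"]`) or CSV coordinates with
an MTX/CSV feature matrix; see `slicealign align --help`.

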