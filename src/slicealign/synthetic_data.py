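"""Synthetic spatial omics slices with known ground truth.

The generator emulates the structure the alignment benchmarks rely on:
spatially clustered cell-type domains, cell-type-specific count expression
(negative-binomial by default, so correlation matching faces realistic
over-dispersed noise), known rigid rotations/translations between slices,
and rectangular clipping to a prescribed overlap fraction.  Every generator
is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_geometry import RigidTransform, Slice, apply_transform

__all__ = ["SimulationSpec", "SlicePair", "generate_slice", "make_pair", "make_serial",
           "expression_mean_field"]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic fixture.

    ``rotation_deg``/``translation`` define the rigid motion applied to
    manufacture the source slice; ``overlap_fraction`` is the fraction of the
    tissue assayed by both slices (1 = full overlap); ``coord_noise_sd`` is
    positional jitter in platform units; ``dispersion`` is the
    negative-binomial over-dispersion (variance = mu + dispersion * mu^2).
    """

    n_spots: int = 300
    n_genes: int = 60
    n_cell_types: int = 5
    layout: str = "gaussian_blobs"  # gaussian_blobs | layered_bands
    expression_model: str = "negative_binomial"  # negative_binomial | poisson
    dispersion: float = 0.5
    coord_noise_sd: float = 0.0
    rotation_deg: float = 0.0
    translation: tuple[float, ...] = (0.0, 0.0)
    overlap_fraction: float = 1.0
    resample_expression: bool = True
    spatial_gradient: float = 0.8
    n_slices: int = 2
    extent: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1]")
        if self.n_spots < self.n_cell_types:
            raise ValueError("need at least one spot per cell type")
        if self.layout not in ("gaussian_blobs", "layered_bands"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.expression_model not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown expression_model {self.expression_model!r}")


@dataclass
class SlicePair:
    """A source/target fixture with its manufacturing ground truth.

    ``truth`` maps tissue-frame coordinates onto the source slice (the
    source was manufactured by applying it), so an aligner should recover
    ``truth.inverse()``.  ``overlap_mask`` flags the source spots inside the
    region assayed by both slices; ``source_origin`` / ``target_origin``
    give each spot's index into the underlying full tissue, so
    ``source_origin[i] == target_origin[j]`` identifies true twins.
    """

    source: Slice
    target: Slice
    truth: RigidTransform
    overlap_mask: np.ndarray
    source_origin: np.ndarray
    target_origin: np.ndarray

    def __iter__(self):
        return iter((self.source, self.target, self.truth, self.overlap_mask))


def _type_means(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-cell-type per-gene mean expression: an independent lognormal
    baseline per type (distinct transcriptional programs) plus a block of
    strongly type-specific marker genes.  The 5x depth factor puts per-spot
    library sizes in the low thousands, as in sequencing-based platforms."""
    means = rng.lognormal(mean=0.0, sigma=0.5, size=(spec.n_cell_types, spec.n_genes)) * 5.0
    markers_per_type = max(1, spec.n_genes // (2 * spec.n_cell_types))
    for t in range(spec.n_cell_types):
        lo = t * markers_per_type
        means[t, lo : lo + markers_per_type] *= 20.0
    return means


def _gradient_dirs(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """One random spatial direction per gene for the smooth expression
    gradients (tissue expression varies continuously in space, which is what
    gives individual spots positional identity beyond their cell type)."""
    angles = rng.uniform(0.0, 2 * np.pi, size=spec.n_genes)
    return np.column_stack([np.cos(angles), np.sin(angles)])


def expression_mean_field(spec: SimulationSpec, coords: np.ndarray, types: np.ndarray,
                          type_means: np.ndarray, grad_dirs: np.ndarray) -> np.ndarray:
    """Per-spot per-gene mean: the cell-type mean modulated log-linearly
    along each gene's spatial gradient direction (positions scaled to
    [-1/2, 1/2] so ``spatial_gradient`` is a fold-change-like amplitude)."""
    pos = coords / spec.extent - 0.5
    modulation = np.exp(spec.spatial_gradient * (pos @ grad_dirs.T))
    return type_means[types] * modulation


def _sample_counts(means: np.ndarray, spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.expression_model == "poisson":
        return rng.poisson(means).astype(float)
    r = 1.0 / spec.dispersion  # gamma-Poisson mixture: var = mu + dispersion*mu^2
    lam = rng.gamma(shape=r, scale=means / r)
    return rng.poisson(lam).astype(float)


def _spot_layout(spec: SimulationSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates and cell-type assignment for one slice."""
    n, c, ext = spec.n_spots, spec.n_cell_types, spec.extent
    if spec.layout == "gaussian_blobs":
        centers = rng.uniform(0.15 * ext, 0.85 * ext, size=(c, 2))
        types = rng.integers(0, c, size=n)
        coords = centers[types] + rng.normal(scale=0.12 * ext, size=(n, 2))
    else:  # layered_bands: laminar strata perpendicular to x, the clip axis
        coords = rng.uniform(0.0, ext, size=(n, 2))
        types = np.clip((coords[:, 0] / ext * c).astype(int), 0, c - 1)
    return coords, types


def generate_slice(spec: SimulationSpec, slice_id: str = "synthetic") -> Slice:
    """One slice with spatially clustered cell-type domains and per-type
    count expression; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    coords, types = _spot_layout(spec, rng)
    means = _type_means(spec, rng)
    dirs = _gradient_dirs(spec, rng)
    features = _sample_counts(expression_mean_field(spec, coords, types, means, dirs), spec, rng)
    return Slice(
        coords=coords,
        features=features,
        feature_names=[f"gene_{i}" for i in range(spec.n_genes)],
        cell_types=[f"type_{t}" for t in types],
        slice_id=slice_id,
    )


def make_pair(spec: SimulationSpec) -> SlicePair:
    """A partially overlapping source/target pair from one tissue.

    One tissue is generated; the target keeps the spots left of an x
    threshold and the source the spots right of another, the two regions
    sized symmetrically so the shared strip holds ``overlap_fraction`` of
    each slice's spots (``overlap_fraction = 1`` leaves both slices
    uncut).  The source then receives coordinate jitter (``coord_noise_sd``),
    is moved by the ground-truth rigid transform, and (by default) has its
    counts re-drawn from the same per-spot mean field so expression matching
    faces independent assay noise.
    """
    rng = np.random.default_rng(spec.seed)
    coords, types = _spot_layout(spec, rng)
    means = _type_means(spec, rng)
    dirs = _gradient_dirs(spec, rng)
    mean_field = expression_mean_field(spec, coords, types, means, dirs)
    target_features = _sample_counts(mean_field, spec, rng)
    names = [f"gene_{i}" for i in range(spec.n_genes)]
    labels = [f"type_{t}" for t in types]

    f = spec.overlap_fraction
    if f < 1.0:
        # source covers [q(t0), max], target [min, q(t0 + f*(1-t0))]; with
        # t0 = (1-f)/(2-f) both slices keep the same number of spots and the
        # shared strip holds fraction f of each
        t0 = (1.0 - f) / (2.0 - f)
        lo = float(np.quantile(coords[:, 0], t0))
        hi = float(np.quantile(coords[:, 0], t0 + f * (1.0 - t0)))
        target_keep = np.nonzero(coords[:, 0] <= hi)[0]
        source_keep = np.nonzero(coords[:, 0] >= lo)[0]
        overlap_mask = coords[source_keep, 0] <= hi
    else:
        target_keep = np.arange(spec.n_spots)
        source_keep = np.arange(spec.n_spots)
        overlap_mask = np.ones(spec.n_spots, dtype=bool)
    if source_keep.size == 0 or target_keep.size == 0:
        raise ValueError("overlap clip removed every spot of one slice")

    target = Slice(coords=coords[target_keep], features=target_features[target_keep],
                   feature_names=names, cell_types=[labels[i] for i in target_keep],
                   slice_id="target")

    truth = RigidTransform.from_angle(spec.rotation_deg, spec.translation)
    noisy = coords + rng.normal(scale=spec.coord_noise_sd, size=coords.shape) \
        if spec.coord_noise_sd > 0 else coords.copy()

    if spec.resample_expression:
        # the source re-assays the same tissue positions: same mean field,
        # independent count draw
        src_features = _sample_counts(mean_field[source_keep], spec, rng)
    else:
        src_features = target_features[source_keep].copy()

    source = Slice(
        coords=apply_transform(truth, noisy[source_keep]),
        features=src_features,
        feature_names=list(names),
        cell_types=[labels[i] for i in source_keep],
        slice_id="source",
    )
    return SlicePair(source=source, target=target, truth=truth,
                     overlap_mask=overlap_mask, source_origin=source_keep,
                     target_origin=target_keep)


def make_serial(spec: SimulationSpec, max_rotation_deg: float = 45.0,
                drift_per_slice: float = 0.04) -> tuple[list[Slice], list[RigidTransform]]:
    """Serial sections with small random rotations and monotone label drift.

    Slice ``t`` is the base tissue moved by a random rotation in
    [0, ``max_rotation_deg``] and a small translation; an increasing
    fraction ``t * drift_per_slice`` of the lowest-y spots is relabeled to
    the first cell type (monotone drift across z) with expression resampled
    to match.  Returns the slices and the per-slice truth transforms
    (base frame -> slice ``t`` frame; slice 0 is the identity).
    """
    if spec.n_slices < 2:
        raise ValueError("need at least 2 serial slices")
    rng = np.random.default_rng(spec.seed)
    coords, types = _spot_layout(spec, rng)
    means = _type_means(spec, rng)
    dirs = _gradient_dirs(spec, rng)
    names = [f"gene_{i}" for i in range(spec.n_genes)]
    y_order = np.argsort(coords[:, 1], kind="stable")
    # resample_expression=False: adjacent sections share one count draw
    # (perfect expression continuity, the clean study condition)
    shared_counts = None
    if not spec.resample_expression:
        shared_counts = _sample_counts(
            expression_mean_field(spec, coords, types, means, dirs), spec, rng
        )

    slices: list[Slice] = []
    truths: list[RigidTransform] = []
    for t in range(spec.n_slices):
        if t == 0:
            truth = RigidTransform.identity(2)
        else:
            ang = rng.uniform(0.0, max_rotation_deg)
            shift = rng.uniform(-0.1 * spec.extent, 0.1 * spec.extent, size=2)
            truth = RigidTransform.from_angle(ang, shift)
        drift_n = int(round(min(t * drift_per_slice, 0.5) * spec.n_spots))
        slice_types = types.copy()
        slice_types[y_order[:drift_n]] = 0
        noisy = coords + rng.normal(scale=spec.coord_noise_sd, size=coords.shape) \
            if spec.coord_noise_sd > 0 else coords
        if shared_counts is not None:
            features = shared_counts.copy()
        else:
            features = _sample_counts(
                expression_mean_field(spec, coords, slice_types, means, dirs), spec, rng
            )
        slices.append(
            Slice(
                coords=apply_transform(truth, noisy),
                features=features,
                feature_names=list(names),
                cell_types=[f"type_{v}" for v in slice_types],
                slice_id=f"serial_{t}",
            )
        )
        truths.append(truth)
    return slices, truths
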