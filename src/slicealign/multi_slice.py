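"""Serial-section stacking and 3D-to-3D alignment.

``serial_stack`` chains pairwise alignments — each slice is registered to
the already-transformed previous slice — assigns evenly spaced z offsets and
merges the sections into one 3D slice.  ``align_3d_to_3d`` runs the same
coarse-to-fine pipeline on two assembled stacks with 3x3 rotation matrices,
optionally after spatial binning to bound memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import RigidTransform, Slice, apply_transform
from .fine import AlignmentResult
from .pipeline import PipelineConfig, align_pair
from .slice_io import bin_slice, harmonize_features

__all__ = ["StackResult", "serial_stack", "align_3d_to_3d"]


@dataclass
class StackResult:
    results: list[AlignmentResult]          # per consecutive pair
    cumulative: list[RigidTransform]        # slice t -> reference frame
    stacked: Slice                          # merged 3D slice


def _harmonize_all(slices: list[Slice]) -> list[Slice]:
    out = list(slices)
    for i in range(1, len(out)):
        out[0], out[i] = harmonize_features(out[0], out[i])
    # second pass so every slice carries the final (smallest) feature set
    return [harmonize_features(out[0], s)[1] for s in out]


def serial_stack(slices: list[Slice], z_spacing: float = 1.0,
                 config: PipelineConfig | None = None,
                 reference: str = "first") -> StackResult:
    """Chain-align an ordered series of 2D sections into a 3D stack.

    Slice ``t+1`` is aligned to the already-transformed slice ``t`` and the
    per-pair composed transforms are accumulated, so every section ends up
    in the reference slice's frame; section ``t`` receives
    ``z_offset = t * z_spacing``.  ``reference='last'`` chains from the
    other end (z offsets keep the original order).
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices to stack")
    if reference not in ("first", "last"):
        raise ValueError("reference must be 'first' or 'last'")
    config = config or PipelineConfig()

    order = list(range(len(slices))) if reference == "first" else list(range(len(slices) - 1, -1, -1))
    work = _harmonize_all([slices[i] for i in order])
    dim = work[0].dim

    results: list[AlignmentResult] = []
    cumulative = [RigidTransform.identity(dim)]
    transformed = [work[0].copy()]
    for t in range(1, len(work)):
        try:
            result, _ = align_pair(work[t], transformed[t - 1], config)
        except Exception as exc:
            raise RuntimeError(f"alignment failed at slice pair {t - 1}->{t}: {exc}") from exc
        results.append(result)
        # the target was already in the reference frame, so the pair's
        # composed transform maps slice t directly into that frame
        cum = result.composed
        cumulative.append(cum)
        transformed.append(work[t].with_coords(apply_transform(cum, work[t].coords)))

    # merge into one 3D slice; z by original serial order
    blocks = []
    cts: list[str] | None = [] if all(s.cell_types is not None for s in work) else None
    feats = []
    for pos, s in enumerate(transformed):
        z = (order[pos] if reference == "last" else pos) * z_spacing
        s.z_offset = z
        blocks.append(np.column_stack([s.coords, np.full(s.n_spots, float(z))]))
        feats.append(s.features)
        if cts is not None:
            cts.extend(s.cell_types)  # type: ignore[arg-type]
    stacked = Slice(
        coords=np.vstack(blocks),
        features=np.vstack(feats),
        feature_names=list(work[0].feature_names),
        cell_types=cts,
        slice_id="stack",
    )
    return StackResult(results=results, cumulative=cumulative, stacked=stacked)


def align_3d_to_3d(stack_a: Slice, stack_b: Slice,
                   config: PipelineConfig | None = None,
                   bin_size: float | None = None) -> AlignmentResult:
    """Align one assembled 3D stack onto another.

    Identical contracts to the 2D pipeline with 3x3 rotations; when
    ``bin_size`` is given both stacks are spatially binned first (features
    summed per bin) to bound the correlation matrix and graph sizes, and the
    transform estimated on the binned clouds applies unchanged to the
    originals.
    """
    if stack_a.dim != 3 or stack_b.dim != 3:
        raise ValueError("both stacks must be 3D")
    if bin_size is not None:
        stack_a = bin_slice(stack_a, bin_size)
        stack_b = bin_slice(stack_b, bin_size)
    result, _ = align_pair(stack_a, stack_b, config)
    return result
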