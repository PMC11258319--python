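"""End-to-end pairwise alignment: harmonize, normalize, coarse, fine."""

from __future__ import annotations

from dataclasses import dataclass, field

from .coarse import PairSet, coarse_align
from .core_geometry import RigidTransform, Slice, apply_transform
from .fine import AlignmentResult, FineConfig, SoftMap, fine_align
import numpy as np

from .slice_io import harmonize_features, normalize_features

__all__ = ["PipelineConfig", "align_pair"]


@dataclass
class PipelineConfig:
    """Configuration of the full coarse-to-fine pipeline."""

    mode: str = "align"  # align | stitch
    normalize: str = "library_log1p"  # none | library_log1p
    run_fine: bool = True
    fine: FineConfig = field(default_factory=FineConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("align", "stitch"):
            raise ValueError(f"mode must be 'align' or 'stitch', got {self.mode!r}")


def align_pair(x: Slice, y: Slice, config: PipelineConfig | None = None
               ) -> tuple[AlignmentResult, PairSet]:
    """Align source ``x`` onto target ``y``.

    Features are harmonized (shared columns) and normalized, the coarse
    correlation/SVD stage produces an initial placement (with overlap
    filtering in ``stitch`` mode), and the graph-embedding fine stage
    refines it unless ``run_fine`` is off.  The returned result's
    ``composed`` transform maps the original source coordinates onto the
    target frame.
    """
    config = config or PipelineConfig()
    xh, yh = harmonize_features(x, y)
    xn = normalize_features(xh, config.normalize) if config.normalize != "none" else xh
    yn = normalize_features(yh, config.normalize) if config.normalize != "none" else yh

    coarse_t, pairset = coarse_align(xn, yn, mode=config.mode)
    x_coarse = xn.with_coords(apply_transform(coarse_t, xn.coords))

    if config.run_fine:
        result = fine_align(x_coarse, yn, config.fine, coarse=coarse_t)
    else:
        identity = RigidTransform.identity(x.dim)
        result = AlignmentResult(
            coarse=coarse_t,
            fine=identity,
            composed=coarse_t,
            transformed_coords=x_coarse.coords,
            loss_trace=[],
            soft_map=SoftMap(m=np.full((x.n_spots, y.n_spots), 1.0 / y.n_spots)),
        )
    return result, pairset
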