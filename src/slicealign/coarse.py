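"""Stage 1: expression-correlation coarse alignment and overlap detection.

Every source spot is matched to the target spot whose expression profile it
correlates with best (Pearson, across the shared features).  In ``stitch``
mode the sorted correlation curve is segmented by change-point detection —
the split minimizing the summed absolute deviation from each segment's
median — and only the high-correlation (left) segment, which concentrates in
the physically shared region, feeds the rigid SVD fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import RigidTransform, Slice, estimate_rigid_transform

__all__ = [
    "PairSet",
    "pairwise_pcc",
    "best_match_pairs",
    "changepoint_split",
    "coarse_align",
    "TooFewPairsError",
    "InsufficientOverlapError",
]


class TooFewPairsError(ValueError):
    """Change-point detection needs at least 4 sorted correlation values."""


class InsufficientOverlapError(ValueError):
    """Fewer surviving pairs than the spatial dimension."""


@dataclass
class PairSet:
    """Candidate one-to-one matches between two slices.

    ``pairs[k] = (i, j)`` matches source spot ``i`` to target spot ``j`` with
    Pearson correlation ``pcc[k]``; ``order`` sorts ``pcc`` descending;
    ``split_index``, when set, is the change point: pairs at sorted positions
    ``< split_index`` are considered inside the overlap region.
    """

    pairs: list[tuple[int, int]]
    pcc: list[float]
    order: np.ndarray = field(default=None)  # type: ignore[assignment]
    split_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.pcc):
            raise ValueError("pairs and pcc lengths differ")
        src = [i for i, _ in self.pairs]
        if len(set(src)) != len(src):
            raise ValueError("each source index may appear at most once")
        if self.order is None:
            # stable sort on negated values: ties keep original pair order
            self.order = np.argsort(-np.asarray(self.pcc), kind="stable")
        if self.split_index is not None and not (1 <= self.split_index <= len(self.pairs) - 1):
            raise ValueError("split_index out of range")

    def kept_pairs(self) -> list[tuple[int, int]]:
        """Pairs surviving the overlap filter (all pairs when no split)."""
        if self.split_index is None:
            return list(self.pairs)
        keep = self.order[: self.split_index]
        return [self.pairs[k] for k in keep]

    def kept_mask(self) -> np.ndarray:
        """Boolean per original pair: inside the kept (overlap) segment."""
        mask = np.ones(len(self.pairs), dtype=bool)
        if self.split_index is not None:
            mask[:] = False
            mask[self.order[: self.split_index]] = True
        return mask

    def to_tsv(self, path) -> None:
        import pandas as pd

        kept = self.kept_mask()
        pd.DataFrame(
            {
                "source_index": [i for i, _ in self.pairs],
                "target_index": [j for _, j in self.pairs],
                "pcc": self.pcc,
                "kept": kept.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


def pairwise_pcc(g_x: np.ndarray, g_y: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between spot feature vectors.

    Each row is centred by its own mean across features; entry ``(i, j)`` is
    the correlation between source spot ``i`` and target spot ``j``.  Rows
    with zero variance get correlation 0 (with a warning) rather than NaN.
    """
    g_x = np.asarray(g_x, dtype=float)
    g_y = np.asarray(g_y, dtype=float)
    if g_x.shape[1] != g_y.shape[1]:
        raise ValueError("feature dimensions differ; harmonize features first")
    if g_x.shape[1] < 2:
        raise ValueError("need at least 2 shared features for a correlation")
    cx = g_x - g_x.mean(axis=1, keepdims=True)
    cy = g_y - g_y.mean(axis=1, keepdims=True)
    sx = np.sqrt((cx**2).sum(axis=1))
    sy = np.sqrt((cy**2).sum(axis=1))
    zx = sx == 0
    zy = sy == 0
    if zx.any() or zy.any():
        warnings.warn(
            f"{int(zx.sum())} source / {int(zy.sum())} target spots have zero "
            "expression variance; their correlations are set to 0"
        )
    num = cx @ cy.T
    denom = np.outer(np.where(zx, 1.0, sx), np.where(zy, 1.0, sy))
    pcc = num / denom
    pcc[zx, :] = 0.0
    pcc[:, zy] = 0.0
    return np.clip(pcc, -1.0, 1.0)


def best_match_pairs(pcc_matrix: np.ndarray) -> PairSet:
    """Match every source spot to its highest-correlation target spot.

    Ties go to the smallest target index; matching is source-to-target only,
    so a target spot may be matched repeatedly.
    """
    pcc_matrix = np.asarray(pcc_matrix, dtype=float)
    if not np.all(np.isfinite(pcc_matrix)):
        raise ValueError("correlation matrix contains non-finite values")
    best_j = np.argmax(pcc_matrix, axis=1)  # argmax returns first (smallest) index on ties
    pairs = [(i, int(j)) for i, j in enumerate(best_j)]
    pcc = [float(pcc_matrix[i, j]) for i, j in pairs]
    return PairSet(pairs=pairs, pcc=pcc)


def changepoint_split(pcc_sorted) -> int:
    """Change point of a descending correlation curve.

    Returns the split ``x'`` minimizing ``cost(left) + cost(right)`` where
    ``cost(segment) = sum |p - median(segment)|``, over all splits leaving at
    least 2 elements on each side.  When all splits cost the same (e.g. a
    constant list) the largest admissible split is returned, keeping the most
    pairs.  The caller keeps the left (high-correlation) segment.
    """
    p = np.asarray(pcc_sorted, dtype=float)
    n = p.size
    if n < 4:
        raise TooFewPairsError(f"change-point detection needs >= 4 pairs, got {n}")
    if np.any(np.diff(p) > 1e-12):
        raise ValueError("input must be sorted in descending order")

    def cost(seg: np.ndarray) -> float:
        return float(np.abs(seg - np.median(seg)).sum())

    splits = np.arange(2, n - 1)
    costs = np.array([cost(p[:s]) + cost(p[s:]) for s in splits])
    best = costs.min()
    # exact ties -> largest admissible split (keep-most rule)
    return int(splits[np.nonzero(costs <= best + 1e-12)[0][-1]])


def coarse_align(x: Slice, y: Slice, mode: str = "align") -> tuple[RigidTransform, PairSet]:
    """Coarse rigid alignment of source ``x`` onto target ``y``.

    ``align`` assumes (near-)full overlap and uses every best-match pair;
    ``stitch`` first drops pairs right of the change point of the descending
    correlation curve, restricting the fit to the detected overlap region.
    Feature matrices must already be harmonized (same columns, same order).
    """
    if mode not in ("align", "stitch"):
        raise ValueError(f"mode must be 'align' or 'stitch', got {mode!r}")
    if x.feature_names != y.feature_names:
        raise ValueError("slices are not feature-harmonized; call harmonize_features first")

    pcc = pairwise_pcc(x.features, y.features)
    pairset = best_match_pairs(pcc)

    if mode == "stitch":
        sorted_pcc = np.asarray(pairset.pcc)[pairset.order]
        pairset.split_index = changepoint_split(sorted_pcc)
        retained = pairset.split_index / len(pairset.pairs)
        if retained < 0.2:
            warnings.warn(
                f"only {retained:.0%} of pairs retained as overlap; stitching "
                "results degrade when overlap regions are below 20%"
            )

    kept = pairset.kept_pairs()
    if len(kept) < x.dim:
        raise InsufficientOverlapError(
            f"only {len(kept)} pairs survive overlap filtering; need >= {x.dim}"
        )
    transform = estimate_rigid_transform(x.coords, y.coords, kept)
    return transform, pairset
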