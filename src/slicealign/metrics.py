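"""Evaluation metrics for slice alignment.

Three pairwise scores plus a cluster-entropy utility:

* **PCC** — mean expression correlation between each source spot and its
  spatially nearest target spot after alignment.
* **CI** (cell-type matching index) — fraction of nearest-neighbor pairs
  sharing a cell-type label.
* **AAS** (alignment angle score) — ``360° − |angle_pred − angle_gt|``;
  higher is better.  The literal form is not wrap-aware (359° vs 1° scores
  worse than 300° vs 1°), so a wrapped variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coarse import pairwise_pcc
from .core_geometry import Slice

__all__ = [
    "MetricsReport",
    "avg_pcc_metric",
    "cell_type_matching_index",
    "alignment_angle_score",
    "cluster_entropy",
    "nearest_target_indices",
    "LabelsRequiredError",
]


class LabelsRequiredError(ValueError):
    """Both slices must carry cell-type labels for the matching index."""


@dataclass
class MetricsReport:
    pcc: float
    ci: float | None
    aas: float | None
    n_pairs: int


def nearest_target_indices(x_coords: np.ndarray, y_coords: np.ndarray) -> np.ndarray:
    """Index of the spatially closest target spot for every source spot;
    distance ties go to the smallest target index."""
    x_coords = np.asarray(x_coords, dtype=float)
    y_coords = np.asarray(y_coords, dtype=float)
    if y_coords.shape[0] == 0:
        raise ValueError("target slice is empty")
    out = np.empty(x_coords.shape[0], dtype=int)
    # chunked to bound the distance-matrix memory; argmin takes the first
    # (smallest-index) minimizer, which is the documented tie rule
    step = max(1, int(4e7) // max(y_coords.shape[0], 1))
    sq_y = (y_coords**2).sum(axis=1)
    for a in range(0, x_coords.shape[0], step):
        chunk = x_coords[a : a + step]
        d2 = ((chunk**2).sum(axis=1)[:, None] + sq_y[None, :] - 2.0 * chunk @ y_coords.T)
        out[a : a + step] = np.argmin(d2, axis=1)
    return out


def avg_pcc_metric(x_aligned: Slice, y: Slice) -> float:
    """Mean expression correlation of each source spot with its nearest
    target spot after alignment; features must be harmonized."""
    if x_aligned.feature_names != y.feature_names:
        raise ValueError("slices are not feature-harmonized")
    nn = nearest_target_indices(x_aligned.coords, y.coords)
    pcc = pairwise_pcc(x_aligned.features, y.features)
    return float(pcc[np.arange(x_aligned.n_spots), nn].mean())


def cell_type_matching_index(x_aligned: Slice, y: Slice) -> float:
    """Fraction of source spots whose nearest target spot shares its label."""
    if x_aligned.cell_types is None or y.cell_types is None:
        raise LabelsRequiredError("both slices must carry cell_type labels")
    nn = nearest_target_indices(x_aligned.coords, y.coords)
    cx = np.asarray(x_aligned.cell_types, dtype=object)
    cy = np.asarray(y.cell_types, dtype=object)
    return float((cx == cy[nn]).mean())


def alignment_angle_score(pred_deg: float, gt_deg: float, wrapped: bool = False) -> float:
    """``360 − |pred − gt|`` in degrees (literal form).

    With ``wrapped=True`` the angular difference is taken on the circle:
    ``360 − min(|Δ| mod 360, 360 − |Δ| mod 360)``, so 359° vs 1° scores 358.
    """
    delta = abs(float(pred_deg) - float(gt_deg))
    if wrapped:
        delta = delta % 360.0
        delta = min(delta, 360.0 - delta)
    return 360.0 - delta


def cluster_entropy(counts) -> np.ndarray:
    """Shannon entropy (natural log) of each cluster's label distribution.

    ``counts`` is a clusters-by-labels non-negative table (array or
    DataFrame); lower entropy means a clearer anatomical structure.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim == 1:
        table = table[None, :]
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    totals = table.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every cluster needs at least one positive count")
    p = table / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def evaluate_pair(x_aligned: Slice, y: Slice, pred_deg: float | None = None,
                  gt_deg: float | None = None) -> MetricsReport:
    """Convenience bundle of the pairwise metrics."""
    ci = None
    if x_aligned.cell_types is not None and y.cell_types is not None:
        ci = cell_type_matching_index(x_aligned, y)
    aas = None
    if pred_deg is not None and gt_deg is not None:
        aas = alignment_angle_score(pred_deg, gt_deg)
    return MetricsReport(
        pcc=avg_pcc_metric(x_aligned, y),
        ci=ci,
        aas=aas,
        n_pairs=x_aligned.n_spots,
    )
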