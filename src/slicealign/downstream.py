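"""Alignment-enabled downstream analyses.

Once a high-resolution slice (e.g. imaging-based, single-cell) and a
low-resolution slice (e.g. sequencing-based spots) share a coordinate frame,
two transfers become possible:

* **Label transfer / deconvolution** — annotate each spot with the dominant
  cell type of the high-resolution cells around it (radius query, k-NN
  fallback for spots with an empty neighborhood).
* **Gene imputation** — predict genes absent from the targeted panel for
  cells outside the shared region by a log-link Poisson regression of the
  untargeted gene (read off the paired nearest spot) on the panel features,
  trained on cells inside the shared region.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from sklearn.linear_model import PoissonRegressor

from .core_geometry import Slice
from .metrics import nearest_target_indices

__all__ = ["label_transfer", "poisson_impute", "impute_gene"]


def _majority(labels: np.ndarray) -> str:
    vals, cnts = np.unique(labels, return_counts=True)
    winners = vals[cnts == cnts.max()]
    return str(sorted(winners)[0])  # lexicographic tie-break


def label_transfer(spots: Slice, cells: Slice, radius: float = 30.0,
                   knn_fallback: int = 3) -> list[str]:
    """Dominant cell type of the cells around each spot.

    Cells within ``radius`` of the spot (post-alignment platform units) vote;
    a spot with an empty circle falls back to its ``knn_fallback`` nearest
    cells.  Majority ties are broken lexicographically.  Deterministic and
    invariant to cell ordering.
    """
    if cells.cell_types is None:
        raise ValueError("high-resolution slice must carry cell_type labels")
    if radius <= 0:
        raise ValueError("radius must be positive")
    labels = np.asarray(cells.cell_types, dtype=object)
    tree = cKDTree(cells.coords)
    neighborhoods = tree.query_ball_point(spots.coords, r=radius)
    out: list[str] = []
    k = min(knn_fallback, cells.n_spots)
    for i, members in enumerate(neighborhoods):
        if not members:
            d = np.linalg.norm(cells.coords - spots.coords[i], axis=1)
            members = np.argsort(d, kind="stable")[:k]
        out.append(_majority(labels[np.asarray(members, dtype=int)]))
    return out


def poisson_impute(cells_overlap_features: np.ndarray, target_counts: np.ndarray,
                   cells_query_features: np.ndarray, alpha: float = 1e-6,
                   max_iter: int = 1000) -> np.ndarray:
    """Predict an untargeted gene for query cells by Poisson regression.

    Fits a log-link Poisson GLM of ``target_counts`` (the untargeted gene's
    expression at the paired spots) on the panel features of the overlap
    cells, with a small L2 penalty ``alpha`` for numerical stability, then
    returns the predicted mean rates for the query cells (strictly
    positive).
    """
    x_train = np.asarray(cells_overlap_features, dtype=float)
    y_train = np.asarray(target_counts, dtype=float).ravel()
    x_query = np.asarray(cells_query_features, dtype=float)
    if x_train.shape[0] != y_train.shape[0]:
        raise ValueError("feature rows and target counts disagree in length")
    if np.any(y_train < 0):
        raise ValueError("target counts must be non-negative")

    if np.ptp(y_train) == 0:
        warnings.warn("constant target gene; fitting an intercept-only model")
        return np.full(x_query.shape[0], max(float(y_train[0]), np.finfo(float).tiny))

    from sklearn.exceptions import ConvergenceWarning

    model = PoissonRegressor(alpha=alpha, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            model.fit(x_train, y_train)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"Poisson regression did not converge within {max_iter} iterations"
            ) from exc
    return model.predict(x_query)


def impute_gene(cells: Slice, spots: Slice, gene: str,
                overlap_mask: np.ndarray, alpha: float = 1e-6) -> np.ndarray:
    """End-to-end imputation of one spot-panel gene onto the cells.

    ``overlap_mask`` flags the cells inside the shared region (for a stitched
    pair, the kept region of the stitching pair set).  Each overlap cell is
    paired with its spatially closest spot; the spot's ``gene`` count is
    regressed on the cell's panel features, and rates are predicted for the
    cells outside the overlap.  Returns a full-length vector: observed-region
    cells carry their paired spot's value, query cells the predicted rate.
    """
    overlap_mask = np.asarray(overlap_mask, dtype=bool)
    if overlap_mask.shape[0] != cells.n_spots:
        raise ValueError("overlap_mask must flag every cell")
    if gene not in spots.feature_names:
        raise KeyError(f"gene {gene!r} not in the spot slice's features")
    g = spots.feature_names.index(gene)

    nn = nearest_target_indices(cells.coords[overlap_mask], spots.coords)
    y_train = spots.features[nn, g]
    pred = poisson_impute(
        cells.features[overlap_mask], y_train, cells.features[~overlap_mask], alpha=alpha
    )
    out = np.empty(cells.n_spots, dtype=float)
    out[overlap_mask] = y_train
    out[~overlap_mask] = pred
    return out
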