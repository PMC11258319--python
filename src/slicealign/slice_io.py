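"""Reading, writing and pre-processing of spatial omics slices.

Supported on-disk dialects: h5ad (coordinates in ``obsm[coords_key]``,
default ``"spatial"``), CSV coordinates plus a MatrixMarket feature matrix
with sidecar row/column name files, and CSV coordinates plus a CSV feature
matrix.  Coordinates are continuous platform units; no axis flipping or
pixel indexing is applied on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core_geometry import Slice

__all__ = [
    "LoaderConfig",
    "load_slice",
    "write_slice",
    "harmonize_features",
    "normalize_features",
    "bin_slice",
    "NoSharedFeaturesError",
]


class NoSharedFeaturesError(ValueError):
    """The two slices have no feature names in common."""


@dataclass
class LoaderConfig:
    format: str = "h5ad"  # h5ad | csv+mtx | csv+csv
    coords_key: str = "spatial"
    celltype_key: str | None = None
    normalize: str = "none"  # none | library_log1p
    n_reduced: int | None = None

    def __post_init__(self) -> None:
        if self.format not in ("h5ad", "csv+mtx", "csv+csv"):
            raise ValueError(f"unknown format {self.format!r}")
        if self.normalize not in ("none", "library_log1p"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.n_reduced is not None and self.n_reduced < 2:
            raise ValueError("n_reduced must be >= 2")


def _dense(x) -> np.ndarray:
    if scipy.sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def load_slice(path: str | Path, config: LoaderConfig | None = None,
               matrix_path: str | Path | None = None) -> Slice:
    """Load one slice.

    For ``csv+mtx`` / ``csv+csv``, ``path`` is the coordinate CSV (header
    ``x,y[,z]``, optional ``cell_type`` column) and ``matrix_path`` the
    feature matrix; a ``.mtx`` matrix expects sidecar ``<stem>_features.txt``
    naming its columns.
    """
    config = config or LoaderConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if config.format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        if config.coords_key not in adata.obsm:
            raise KeyError(
                f"coordinates slot {config.coords_key!r} missing from obsm "
                f"(present: {list(adata.obsm)})"
            )
        coords = np.asarray(adata.obsm[config.coords_key], dtype=float)
        features = _dense(adata.X)
        names = list(map(str, adata.var_names))
        cts = None
        key = config.celltype_key or ("cell_type" if "cell_type" in adata.obs else None)
        if key is not None and key in adata.obs:
            cts = list(map(str, adata.obs[key]))
        z_offset = adata.uns.get("z_offset") if hasattr(adata, "uns") else None
    else:
        coord_df = pd.read_csv(path)
        axes = [a for a in ("x", "y", "z") if a in coord_df.columns]
        if len(axes) < 2:
            raise KeyError(f"coordinate CSV must have x,y[,z] columns, found {list(coord_df.columns)}")
        coords = coord_df[axes].to_numpy(dtype=float)
        cts = None
        key = config.celltype_key or "cell_type"
        if key in coord_df.columns:
            cts = list(map(str, coord_df[key]))
        if matrix_path is None:
            raise ValueError("csv formats require matrix_path")
        matrix_path = Path(matrix_path)
        if config.format == "csv+mtx":
            features = _dense(scipy.io.mmread(matrix_path))
            names_file = matrix_path.with_name(matrix_path.stem + "_features.txt")
            if names_file.exists():
                names = names_file.read_text().split()
            else:
                names = [f"feature_{i}" for i in range(features.shape[1])]
        else:
            feat_df = pd.read_csv(matrix_path)
            names = list(map(str, feat_df.columns))
            features = feat_df.to_numpy(dtype=float)
        z_offset = None

    if not np.all(np.isfinite(coords)):
        raise ValueError(f"{path}: non-finite coordinates")
    if features.shape[0] != coords.shape[0]:
        raise ValueError(
            f"{path}: row-count mismatch — {coords.shape[0]} coordinate rows vs "
            f"{features.shape[0]} feature rows"
        )
    s = Slice(coords=coords, features=features, feature_names=names,
              cell_types=cts, slice_id=path.stem,
              z_offset=float(z_offset) if z_offset is not None else None)
    if config.normalize != "none":
        s = normalize_features(s, config.normalize)
    return s


def write_slice(s: Slice, path: str | Path, coords_key: str = "spatial") -> None:
    """Write a slice as h5ad (``.h5ad``) or as coordinate CSV (``.csv``)."""
    path = Path(path)
    if path.suffix == ".h5ad":
        import anndata

        adata = anndata.AnnData(
            X=np.asarray(s.features, dtype=np.float64),
            obs=pd.DataFrame(
                {"cell_type": s.cell_types} if s.cell_types is not None else {},
                index=[f"spot_{i}" for i in range(s.n_spots)],
            ),
            var=pd.DataFrame(index=s.feature_names),
        )
        adata.obsm[coords_key] = s.coords
        if s.z_offset is not None:
            adata.uns["z_offset"] = float(s.z_offset)
        adata.write_h5ad(path)
    else:
        cols = {a: s.coords[:, i] for i, a in enumerate("xyz"[: s.dim])}
        if s.cell_types is not None:
            cols["cell_type"] = s.cell_types
        pd.DataFrame(cols).to_csv(path, index=False)


def harmonize_features(x: Slice, y: Slice) -> tuple[Slice, Slice]:
    """Restrict both slices to their shared features, lexicographic order.

    Idempotent; raises :class:`NoSharedFeaturesError` when the name sets are
    disjoint (cross-modality data should instead supply a pre-computed joint
    embedding as the feature matrix).
    """
    shared = sorted(set(x.feature_names) & set(y.feature_names))
    if not shared:
        raise NoSharedFeaturesError(
            "slices share no feature names; for cross-modality pairs supply a "
            "pre-computed joint embedding as the feature matrix of both slices"
        )

    def _restrict(s: Slice) -> Slice:
        pos = {n: i for i, n in enumerate(s.feature_names)}
        cols = [pos[n] for n in shared]
        out = s.copy()
        out.features = s.features[:, cols]
        out.feature_names = list(shared)
        return out

    return _restrict(x), _restrict(y)


def normalize_features(s: Slice, mode: str = "library_log1p") -> Slice:
    """Depth-normalize expression.

    ``library_log1p`` scales each row to the median library size of the slice
    and applies log(1+x); raw-count Pearson correlations are otherwise
    dominated by sequencing depth.  ``none`` is the identity.
    """
    if mode == "none":
        return s.copy()
    if mode != "library_log1p":
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = s.copy()
    lib = out.features.sum(axis=1)
    zero = lib <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero feature rows left as zeros")
    target = np.median(lib[~zero]) if (~zero).any() else 1.0
    scale = np.where(zero, 1.0, target / np.where(zero, 1.0, lib))
    out.features = np.log1p(out.features * scale[:, None])
    return out


def bin_slice(s: Slice, bin_size: float) -> Slice:
    """Spatially down-sample by square (cube) binning.

    Spots are grouped by ``floor(coord / bin_size)`` per axis with the origin
    fixed at coordinate 0; each non-empty bin becomes one spot at its member
    centroid with summed features and the majority cell-type label (ties
    broken lexicographically).  Total feature mass is conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    keys = np.floor(s.coords / float(bin_size)).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_bins = uniq.shape[0]

    counts = np.bincount(inverse, minlength=n_bins).astype(float)
    coords = np.zeros((n_bins, s.dim))
    for d in range(s.dim):
        coords[:, d] = np.bincount(inverse, weights=s.coords[:, d], minlength=n_bins) / counts
    features = np.zeros((n_bins, s.n_features))
    for f in range(s.n_features):
        features[:, f] = np.bincount(inverse, weights=s.features[:, f], minlength=n_bins)

    cts = None
    if s.cell_types is not None:
        cts = []
        labels = np.asarray(s.cell_types, dtype=object)
        for b in range(n_bins):
            members = labels[inverse == b]
            vals, cnts = np.unique(members, return_counts=True)
            cts.append(str(sorted(vals[cnts == cnts.max()])[0]))
    return Slice(coords=coords, features=features, feature_names=list(s.feature_names),
                 cell_types=cts, slice_id=f"{s.slice_id}_bin{bin_size:g}", z_offset=s.z_offset)
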