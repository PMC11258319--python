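"""Point-cloud data model and rigid-transform machinery.

A :class:`Slice` is one tissue section profiled by a spatial omics platform:
``N`` spots/cells with ``D``-dimensional coordinates (``D`` in {2, 3}) and an
``N x F`` non-negative feature matrix (gene counts, gene scores, protein
intensities, or a pre-computed joint embedding).  A :class:`RigidTransform`
is a proper rotation plus a translation; reflections are forbidden because a
physical tissue section cannot be mirrored by remounting.

Rigid estimation follows the classical Kabsch / orthogonal-Procrustes
closed form: the cross-covariance of paired, centroid-centred coordinates is
decomposed by SVD and the rotation is reassembled from the singular vectors,
with the standard determinant correction so the optimum is searched over
proper rotations only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Slice",
    "RigidTransform",
    "apply_transform",
    "compose",
    "estimate_rigid_transform",
    "rotation_angle",
    "DimensionalityError",
    "InsufficientCorrespondenceError",
    "DegenerateGeometryError",
]


class DimensionalityError(ValueError):
    """Transform and coordinates (or two transforms) disagree in dimension."""


class InsufficientCorrespondenceError(ValueError):
    """Fewer correspondence pairs than the spatial dimension."""


class DegenerateGeometryError(ValueError):
    """Pairs are collinear (2D) / coplanar (3D); rotation is not identifiable."""


@dataclass
class Slice:
    """One spatial omics section.

    Parameters
    ----------
    coords
        ``N x D`` spatial coordinates in continuous platform units.
    features
        ``N x F`` non-negative feature matrix, row-aligned with ``coords``.
    feature_names
        ``F`` unique feature (gene/protein) names.
    cell_types
        Optional ``N`` categorical labels.
    slice_id
        Identifier used in provenance columns of exported tables.
    z_offset
        z coordinate assigned to a 2D slice when stacked into a 3D volume.
    """

    coords: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    cell_types: list[str] | None = None
    slice_id: str = "slice"
    z_offset: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be N x D with D in {{2, 3}}, got shape {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("slice must contain at least one spot")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite entries")
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"features must have one row per spot: coords {self.coords.shape[0]} rows, "
                f"features shape {self.features.shape}"
            )
        self.feature_names = [str(n) for n in self.feature_names]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal the number of feature columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names contains duplicates")
        if self.cell_types is not None:
            self.cell_types = [str(c) for c in self.cell_types]
            if len(self.cell_types) != self.coords.shape[0]:
                raise ValueError("cell_types length must equal the number of spots")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "Slice":
        return Slice(
            coords=self.coords.copy(),
            features=self.features.copy(),
            feature_names=list(self.feature_names),
            cell_types=list(self.cell_types) if self.cell_types is not None else None,
            slice_id=self.slice_id,
            z_offset=self.z_offset,
        )

    def with_coords(self, coords: np.ndarray) -> "Slice":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float)
        if out.coords.shape[0] != self.n_spots:
            raise ValueError("replacement coords must keep the number of spots")
        return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation ``R`` plus translation ``T``; maps x to R @ x + T."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float).ravel()
        d = rot.shape[0]
        if rot.shape != (d, d) or d not in (2, 3):
            raise ValueError(f"rotation must be DxD with D in {{2,3}}, got {rot.shape}")
        if tra.shape != (d,):
            raise ValueError("translation length must equal the rotation dimension")
        if not np.allclose(rot.T @ rot, np.eye(d), atol=1e-8):
            raise ValueError("rotation is not orthogonal within 1e-8")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1); reflections are not admitted")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @property
    def dim(self) -> int:
        return self.rotation.shape[0]

    @classmethod
    def identity(cls, dim: int) -> "RigidTransform":
        return cls(np.eye(dim), np.zeros(dim))

    @classmethod
    def from_angle(cls, angle_deg: float, translation: Sequence[float] = (0.0, 0.0)) -> "RigidTransform":
        """2D rotation by ``angle_deg`` counter-clockwise plus a translation."""
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(rot, np.asarray(translation, dtype=float))

    @classmethod
    def from_axis_angle(cls, axis: Sequence[float], angle_deg: float,
                        translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """3D rotation by ``angle_deg`` about ``axis`` (Rodrigues formula)."""
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        th = np.deg2rad(angle_deg)
        k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        rot = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        return cls(rot, np.asarray(translation, dtype=float))

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as a small JSON document; 17 significant digits round-trip
        float64 bit-exactly."""
        doc = {
            "dim": self.dim,
            "rotation": [float(f"{v:.17g}") for v in self.rotation.ravel()],
            "translation": [float(f"{v:.17g}") for v in self.translation],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RigidTransform":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        d = int(doc["dim"])
        return cls(np.array(doc["rotation"], dtype=float).reshape(d, d),
                   np.array(doc["translation"], dtype=float))


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply ``R @ x + T`` to every row of ``coords``; the input is unchanged."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != t.dim:
        raise DimensionalityError(
            f"transform is {t.dim}D but coordinates have shape {coords.shape}"
        )
    return coords @ t.rotation.T + t.translation


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``first`` then ``second``."""
    if first.dim != second.dim:
        raise DimensionalityError(f"cannot compose {first.dim}D with {second.dim}D transform")
    return RigidTransform(
        second.rotation @ first.rotation,
        second.rotation @ first.translation + second.translation,
    )


def estimate_rigid_transform(
    src_coords: np.ndarray,
    dst_coords: np.ndarray,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> RigidTransform:
    """Least-squares proper rigid transform mapping paired source spots onto
    their targets.

    The cross-covariance ``H = sum_i (s_i - s̄)(d_i - d̄)ᵀ`` over the pairs is
    decomposed ``H = U Σ Vᵀ``; the rotation is ``V Uᵀ``, with the column of
    ``V`` belonging to the smallest singular value negated whenever the raw
    product has determinant −1, and the translation places the source
    centroid onto the target centroid.

    Parameters
    ----------
    src_coords, dst_coords
        Coordinate matrices; ``pairs`` indexes into them.
    pairs
        ``(i, j)`` correspondences; ``None`` pairs rows identically (requires
        equal lengths).
    """
    src_coords = np.asarray(src_coords, dtype=float)
    dst_coords = np.asarray(dst_coords, dtype=float)
    if src_coords.shape[1] != dst_coords.shape[1]:
        raise DimensionalityError("source and target coordinate dimensions differ")
    d = src_coords.shape[1]
    if pairs is None:
        if src_coords.shape[0] != dst_coords.shape[0]:
            raise ValueError("identity pairing needs equal numbers of rows")
        src = src_coords
        dst = dst_coords
    else:
        idx = np.asarray(list(pairs), dtype=int)
        if idx.size == 0:
            raise InsufficientCorrespondenceError(f"need at least {d} pairs, got 0")
        src = src_coords[idx[:, 0]]
        dst = dst_coords[idx[:, 1]]
    n = src.shape[0]
    if n < d:
        raise InsufficientCorrespondenceError(f"need at least {d} pairs, got {n}")

    src_centroid = src.mean(axis=0)
    dst_centroid = dst.mean(axis=0)
    h = (src - src_centroid).T @ (dst - dst_centroid)

    u, s, vt = np.linalg.svd(h)
    v = vt.T
    # collinear (2D) / coplanar (3D) pairs leave the rotation unidentifiable
    scale = max(s[0], 1.0)
    if np.sum(s > 1e-10 * scale) < d:
        raise DegenerateGeometryError(
            "correspondence pairs are collinear/coplanar; the rotation is not "
            "identifiable — provide pairs spanning the tissue plane"
        )
    rot = v @ u.T
    if np.linalg.det(rot) < 0:
        v_fix = v.copy()
        v_fix[:, -1] *= -1.0
        rot = v_fix @ u.T
    return RigidTransform(rot, dst_centroid - rot @ src_centroid)


def rotation_angle(t: RigidTransform) -> float:
    """Rotation angle in degrees.

    2D: counter-clockwise angle in [0°, 360°).  3D: axis-angle magnitude from
    the trace formula, in [0°, 180°] (per-axis Euler angles are deliberately
    not exposed — the decomposition convention is ambiguous).
    """
    r = t.rotation
    if t.dim == 2:
        ang = np.degrees(np.arctan2(r[1, 0], r[0, 0]))
        return float(ang % 360.0)
    cos_th = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_th)))
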