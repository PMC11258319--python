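"""Stage 2: graph-embedding fine alignment.

After the coarse stage has placed the source slice roughly on the target,
this stage learns permutation-invariant node embeddings of each slice's
spatial and omics neighborhoods with a dynamic-graph edge-convolution
network (the k-NN graph is recomputed in embedding space before every layer
after the first).  A row-stochastic soft correspondence map between the two
slices is read off the embeddings; the soft map pulls each source spot
toward a weighted average of target positions, an unsupervised loss mixes
expression dissimilarity and spatial distance under distance-decayed
(softmin) attention, and the network weights are trained by Adam.  A final
rigid SVD fit between the coarse coordinates and the soft-mapped
coordinates yields the fine transform.

Weights are shared between the two slices within each branch (one network
for spatial input, one for omics input), so both slices are embedded by the
same function and their embeddings live in a common space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .coarse import pairwise_pcc
from .core_geometry import (
    RigidTransform,
    Slice,
    apply_transform,
    compose,
    estimate_rigid_transform,
)

__all__ = [
    "FineConfig",
    "NeighborGraph",
    "SoftMap",
    "AlignmentResult",
    "NetworkWeights",
    "build_knn_graph",
    "dgcnn_embed",
    "soft_map",
    "softmin_weights",
    "fine_loss",
    "fine_align",
    "TooFewPointsError",
]


class TooFewPointsError(ValueError):
    """k-NN graph construction needs strictly more points than neighbors."""


@dataclass
class FineConfig:
    """Hyperparameters of the fine stage.

    ``alpha`` weights the expression term of the loss against the spatial
    term; ``tau`` is the softmin temperature in normalized coordinate units
    (coordinates are rescaled so the median k-NN distance is 1 before
    training and the fitted transform is mapped back afterwards, so one
    default is meaningful across platforms).  Defaults sit at the midpoints
    of the robustness grid (lr 0.01/0.05/0.1, epochs 50/100/200, k 5/10/15,
    alpha 0.1/0.3/0.5), i.e. lr 0.05, epochs 100, k 10, alpha 0.3.
    """

    k: int = 10
    alpha: float = 0.3
    lr: float = 0.05
    epochs: int = 100
    tau: float = 1.0
    layers: int = 3
    channels: tuple[int, ...] = (64, 64, 128)
    pca_dims: int | None = 50
    sim_temp: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) != self.layers:
            raise ValueError("len(channels) must equal layers")


@dataclass
class NeighborGraph:
    """Exact k-NN edge sets: ``edges[i]`` holds the k neighbors of node i."""

    edges: np.ndarray  # N x k int
    metric_space: str = "spatial"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        n, k = self.edges.shape
        if np.any(self.edges < 0) or np.any(self.edges >= n):
            raise ValueError("neighbor indices out of range")
        if np.any(self.edges == np.arange(n)[:, None]):
            raise ValueError("self-loops are not allowed")

    @property
    def k(self) -> int:
        return self.edges.shape[1]


@dataclass
class SoftMap:
    """Row-stochastic probabilistic correspondence from source to target."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0):
            raise ValueError("soft map entries must be non-negative")
        if not np.allclose(self.m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft map rows must sum to 1 within 1e-6")


@dataclass
class AlignmentResult:
    coarse: RigidTransform
    fine: RigidTransform
    composed: RigidTransform
    transformed_coords: np.ndarray
    loss_trace: list[float]
    soft_map: SoftMap
    diagnostics: dict = field(default_factory=dict)


def build_knn_graph(points: np.ndarray, k: int, metric_space: str = "spatial") -> NeighborGraph:
    """Exact Euclidean k nearest neighbors, self excluded, distance ties
    broken by the smaller index."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n <= k:
        raise TooFewPointsError(f"need more than k={k} points, got {n}")
    edges = _knn_indices(points, k)
    return NeighborGraph(edges=edges, metric_space=metric_space)


def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    sq = (points**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
    np.fill_diagonal(d2, np.inf)
    # stable sort: equal distances keep ascending index order
    return np.argsort(d2, axis=1, kind="stable")[:, :k]


class NetworkWeights:
    """Per-layer edge-MLP parameters of one embedding network.

    Layer ``l`` maps the edge feature ``(x_i, x_j - x_i)`` of width
    ``2 * C_{l-1}`` through a linear map plus leaky ReLU to ``C_l`` channels.
    """

    def __init__(self, layers: list[tuple[ad.Tensor, ad.Tensor]]):
        self.layers = layers

    @classmethod
    def init(cls, in_dim: int, channels: tuple[int, ...], rng: np.random.Generator) -> "NetworkWeights":
        layers = []
        c_prev = in_dim
        for c_out in channels:
            fan_in = 2 * c_prev
            bound = np.sqrt(6.0 / (fan_in + c_out))  # Glorot uniform
            w = ad.Tensor(rng.uniform(-bound, bound, size=(fan_in, c_out)), requires_grad=True)
            b = ad.Tensor(np.zeros(c_out), requires_grad=True)
            layers.append((w, b))
            c_prev = c_out
        return cls(layers)

    def params(self) -> list[ad.Tensor]:
        return [t for pair in self.layers for t in pair]


def _edge_conv(h: ad.Tensor, edges: np.ndarray, w: ad.Tensor, b: ad.Tensor) -> ad.Tensor:
    """One edge-convolution layer: leaky-ReLU MLP on (x_i, x_j - x_i) per
    edge, channel-wise max over each node's neighbors."""
    n, k = edges.shape
    hi = h.take_rows(np.repeat(np.arange(n), k))      # (n*k, C)
    hj = h.take_rows(edges.reshape(-1))               # (n*k, C)
    edge_feat = ad.concatenate([hi, hj - hi], axis=1)  # (n*k, 2C)
    out = (edge_feat @ w + b).leaky_relu(0.2)          # (n*k, C_out)
    return out.reshape(n, k, -1).max(axis=1)           # (n, C_out)


def _dgcnn_forward(values: ad.Tensor, graph_seed: NeighborGraph,
                   weights: NetworkWeights, k: int) -> ad.Tensor:
    """L edge-conv layers with dynamic graph updates; returns the
    concatenation of every layer's output."""
    h = values
    edges = graph_seed.edges
    outputs = []
    for li, (w, b) in enumerate(weights.layers):
        if li > 0:
            edges = _knn_indices(h.data, k)  # dynamic update in embedding space
        h = _edge_conv(h, edges, w, b)
        if not np.all(np.isfinite(h.data)):
            raise FloatingPointError(f"non-finite embedding values at layer {li}")
        outputs.append(h)
    return ad.concatenate(outputs, axis=1)


def dgcnn_embed(values: np.ndarray, graph_seed: NeighborGraph,
                config: FineConfig, weights: NetworkWeights) -> np.ndarray:
    """Embed every node; output width is the sum of the layer channels."""
    values = np.asarray(values, dtype=float)
    out = _dgcnn_forward(ad.Tensor(values), graph_seed, weights, config.k)
    return out.data


def soft_map(f_x: np.ndarray, f_y: np.ndarray) -> SoftMap:
    """Row-softmax of the embedding similarity ``F_X @ F_Yᵀ``: each source
    spot gets a probability distribution over target spots."""
    f_x = np.asarray(f_x, dtype=float)
    f_y = np.asarray(f_y, dtype=float)
    if f_x.shape[1] != f_y.shape[1]:
        raise ValueError("embedding widths differ")
    s = f_x @ f_y.T
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return SoftMap(m=e / e.sum(axis=1, keepdims=True))


def softmin_weights(dist_row: np.ndarray, tau: float) -> np.ndarray:
    """Distance-decayed attention weights ``exp(-d/τ) / Σ exp(-d/τ)``,
    max-shift stabilized; nearer targets receive more weight."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    d = np.asarray(dist_row, dtype=float)
    z = -d / tau
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(np.maximum(d2, 0.0))


def fine_loss(coords_x: np.ndarray, y: Slice | np.ndarray, pcc_matrix: np.ndarray,
              alpha: float, tau: float) -> float:
    """Unsupervised alignment loss.

    ``(1 / (N_X N_Y)) Σ_i Σ_j softmin_ij · [α(1 − PCC_ij) + (1−α)·Dis_ij]``
    where ``Dis`` is the Euclidean distance between the current source
    coordinates and the target coordinates and the softmin weights are
    computed per source spot over the targets.
    """
    coords_y = y.coords if isinstance(y, Slice) else np.asarray(y, dtype=float)
    coords_x = np.asarray(coords_x, dtype=float)
    pcc_matrix = np.asarray(pcc_matrix, dtype=float)
    if pcc_matrix.shape != (coords_x.shape[0], coords_y.shape[0]):
        raise ValueError("pcc_matrix shape does not match the coordinate sets")
    dist = _pairwise_dist(coords_x, coords_y)
    w = np.vstack([softmin_weights(row, tau) for row in dist])
    cost = alpha * (1.0 - pcc_matrix) + (1.0 - alpha) * dist
    return float((w * cost).sum() / (coords_x.shape[0] * coords_y.shape[0]))


def _fine_loss_tensor(coords_x: ad.Tensor, coords_y: np.ndarray,
                      pcc_matrix: np.ndarray, alpha: float, tau: float) -> ad.Tensor:
    """Differentiable twin of :func:`fine_loss` (gradient flows through the
    source coordinates, i.e. through the soft map and the network)."""
    n_x, n_y = pcc_matrix.shape
    sq_x = (coords_x * coords_x).sum(axis=1, keepdims=True)          # (n_x, 1)
    sq_y = ad.Tensor((coords_y**2).sum(axis=1)[None, :])             # (1, n_y)
    cross = coords_x @ ad.Tensor(coords_y.T)
    # clamp tiny negative cancellation error before the sqrt
    d2 = (sq_x + sq_y - 2.0 * cross).leaky_relu(0.0)
    dist = (d2 + ad.Tensor(np.full((n_x, n_y), 1e-12))).sqrt()
    w = (-(dist * (1.0 / tau))).softmax_rows()
    cost = ad.Tensor(alpha * (1.0 - pcc_matrix)) + dist * (1.0 - alpha)
    return (w * cost).sum() * (1.0 / (n_x * n_y))


def _normalize_coords(coords_x: np.ndarray, coords_y: np.ndarray, k: int):
    """Center on the joint centroid and rescale so the median k-NN distance
    is 1; returns (norm_x, norm_y, center, scale)."""
    center = np.vstack([coords_x, coords_y]).mean(axis=0)
    cx = coords_x - center
    cy = coords_y - center
    dists = []
    for c in (cx, cy):
        sq = (c**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (c @ c.T)
        np.fill_diagonal(d2, np.inf)
        kk = min(k, c.shape[0] - 1)
        part = np.partition(d2, kk - 1, axis=1)[:, :kk]
        dists.append(np.sqrt(np.maximum(part, 0.0)).ravel())
    scale = float(np.median(np.concatenate(dists)))
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    return cx / scale, cy / scale, center, scale


def _joint_pca(feat_x: np.ndarray, feat_y: np.ndarray, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint PCA of the stacked feature matrices (deterministic full SVD)."""
    stacked = np.vstack([feat_x, feat_y])
    stacked = stacked - stacked.mean(axis=0)
    dims = min(dims, min(stacked.shape) - 1)
    _, _, vt = np.linalg.svd(stacked, full_matrices=False)
    proj = stacked @ vt[:dims].T
    return proj[: feat_x.shape[0]], proj[feat_x.shape[0]:]


def fine_align(x_coarse: Slice, y: Slice, config: FineConfig | None = None,
               coarse: RigidTransform | None = None) -> AlignmentResult:
    """Refine a coarse placement of ``x_coarse`` onto ``y``.

    Trains the spatial and omics embedding networks (weights shared between
    the two slices per branch) for ``config.epochs`` epochs; each epoch
    embeds both slices, forms the soft map, pulls the source to the
    soft-mapped coordinates and backpropagates the loss.  The fine rigid
    transform is then fitted from the coarse coordinates to the final
    soft-mapped coordinates with identity pairing.

    ``coarse`` (identity when omitted) is only carried into the result for
    composition; ``x_coarse.coords`` must already be coarse-aligned.
    """
    config = config or FineConfig()
    n_x, n_y = x_coarse.n_spots, y.n_spots
    if min(n_x, n_y) <= config.k:
        raise TooFewPointsError(
            f"k={config.k} neighbors need more than k spots per slice (have {n_x}, {n_y})"
        )
    if coarse is None:
        coarse = RigidTransform.identity(x_coarse.dim)

    rng = np.random.default_rng(config.seed)

    sx, sy, center, scale = _normalize_coords(x_coarse.coords, y.coords, config.k)

    feat_x, feat_y = x_coarse.features, y.features
    if config.pca_dims is not None and feat_x.shape[1] > config.pca_dims:
        omics_x, omics_y = _joint_pca(feat_x, feat_y, config.pca_dims)
    else:
        omics_x, omics_y = feat_x.astype(float), feat_y.astype(float)
    # standardize omics inputs so both branches contribute on the same scale
    om_scale = max(np.abs(np.vstack([omics_x, omics_y])).max(), 1e-12)
    omics_x = omics_x / om_scale
    omics_y = omics_y / om_scale

    pcc = np.clip(pairwise_pcc(feat_x, feat_y), -1.0, 1.0) if feat_x.shape[1] >= 2 else np.zeros((n_x, n_y))

    net_spatial = NetworkWeights.init(sx.shape[1], config.channels, rng)
    net_omics = NetworkWeights.init(omics_x.shape[1], config.channels, rng)
    # trainable sharpness of the correspondence softmax: starts at
    # 1/sim_temp and grows if concentrating the map lowers the loss
    log_scale = ad.Tensor(np.array([[np.log(1.0 / config.sim_temp)]]), requires_grad=True)
    params = net_spatial.params() + net_omics.params() + [log_scale]
    opt = ad.Adam(params, lr=config.lr)

    graph_sx = build_knn_graph(sx, config.k, "spatial")
    graph_sy = build_knn_graph(sy, config.k, "spatial")
    graph_ox = build_knn_graph(omics_x, config.k, "omics")
    graph_oy = build_knn_graph(omics_y, config.k, "omics")

    loss_trace: list[float] = []
    rowsum_dev: list[float] = []
    m_data = np.full((n_x, n_y), 1.0 / n_y)

    def _unit_rows(t: ad.Tensor) -> ad.Tensor:
        norm = ((t * t).sum(axis=1, keepdims=True) + ad.Tensor([[1e-12]])).sqrt()
        return t / norm

    def forward():
        ex_s = _dgcnn_forward(ad.Tensor(sx), graph_sx, net_spatial, config.k)
        ey_s = _dgcnn_forward(ad.Tensor(sy), graph_sy, net_spatial, config.k)
        ex_o = _dgcnn_forward(ad.Tensor(omics_x), graph_ox, net_omics, config.k)
        ey_o = _dgcnn_forward(ad.Tensor(omics_y), graph_oy, net_omics, config.k)
        # per-branch unit norms: spatial and omics neighborhoods contribute
        # equally to the similarity, and unit-norm embeddings keep the softmax
        # away from saturation (the similarity is cosine with temperature)
        f_x = ad.concatenate([_unit_rows(ex_s), _unit_rows(ex_o)], axis=1)
        f_y = ad.concatenate([_unit_rows(ey_s), _unit_rows(ey_o)], axis=1)
        sim = (f_x @ f_y.T) * (log_scale.exp() * 0.5)
        m = sim.softmax_rows()
        mapped = m @ ad.Tensor(sy)
        return m, mapped

    for epoch in range(config.epochs):
        opt.zero_grad()
        m, mapped = forward()
        loss = _fine_loss_tensor(mapped, sy, pcc, config.alpha, config.tau)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise FloatingPointError(
                f"loss became non-finite at epoch {epoch}; trace so far: {loss_trace}"
            )
        loss.backward()
        opt.step()
        loss_trace.append(lval)
        rowsum_dev.append(float(np.abs(m.data.sum(axis=1) - 1.0).max()))
        m_data = m.data

    # final mapped coordinates under the trained weights
    m_final, mapped_final = forward()
    m_data = m_final.data
    mapped_orig = mapped_final.data * scale + center

    fine = estimate_rigid_transform(x_coarse.coords, mapped_orig, pairs=None)
    # guard: accept the refinement only if it lowers the alignment objective
    # evaluated at rigid configurations (restricted to rigid transforms the
    # objective is free of the soft map's shrinkage bias, so this comparison
    # is meaningful); otherwise keep the coarse placement
    loss_at_coarse = fine_loss(sx, sy, pcc, config.alpha, config.tau)
    refined_norm = (apply_transform(fine, x_coarse.coords) - center) / scale
    loss_at_fine = fine_loss(refined_norm, sy, pcc, config.alpha, config.tau)
    accepted = loss_at_fine < loss_at_coarse
    if not accepted:
        fine = RigidTransform.identity(x_coarse.dim)
    composed = compose(coarse, fine)
    return AlignmentResult(
        coarse=coarse,
        fine=fine,
        composed=composed,
        transformed_coords=apply_transform(fine, x_coarse.coords),
        loss_trace=loss_trace,
        soft_map=SoftMap(m=m_data),
        diagnostics={
            "softmap_rowsum_max_dev": rowsum_dev,
            "coord_scale": scale,
            "coord_center": center.tolist(),
            "fine_accepted": bool(accepted),
            "rigid_loss_at_coarse": float(loss_at_coarse),
            "rigid_loss_at_fine": float(loss_at_fine),
        },
    )
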