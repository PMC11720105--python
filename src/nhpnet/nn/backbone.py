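"""Set-abstraction backbone regressing a raw 3x3 orientation matrix.

Architecture: two set-abstraction blocks (SAB), each performing

  1. farthest point sampling (FPS) — greedy centroid selection maximizing the
     minimum distance to the already-selected set, giving uniform coverage;
  2. radius grouping — the neighbourhood of each centroid within radius r,
     truncated/padded to a fixed group size so tensors stay rectangular;
  3. a density-corrected point convolution — for centroid i with group G_i,

        f'_i = sum_{p_j in G_i}  W(p_j - p'_i) * f_j / rho(p_j),

     where W is a small learnable MLP on the 3D relative offset and rho is a
     fixed Gaussian kernel-density estimate of the local point density
     (division by rho corrects for non-uniform sampling). The sum of outer
     products f_j/rho_j (x) W(offset) is flattened and linearly projected to
     the block's output width, followed by a rectifier.

A global max pool over the surviving centroids yields an order-invariant
descriptor, and a fully connected head regresses the 9 matrix elements
(row-major). The raw output is *not* orthogonalized during training; the SVD
projection onto SO(3) is applied only at inference.

Everything is NumPy with hand-written reverse-mode gradients; the geometric
structure (FPS indices, groups, offsets, densities) depends only on the input
cloud, not on the parameters, so it is computed once per cloud and reused
across epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SABConfig",
    "NetworkConfig",
    "NHPNet",
    "farthest_point_sample",
    "radius_group",
    "kde_density",
    "pointconv",
    "param_shapes",
    "count_parameters",
    "init_params",
]


@dataclass(frozen=True)
class SABConfig:
    """One set-abstraction block; radius/bandwidth are unit-sphere fractions."""

    n_centroids: int
    radius: float
    max_group_size: int
    out_channels: int
    weightnet_width: int = 16
    density_bandwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.max_group_size < 1 or self.n_centroids < 1:
            raise ValueError("invalid SAB configuration")


@dataclass(frozen=True)
class NetworkConfig:
    sab1: SABConfig = field(
        default_factory=lambda: SABConfig(512, 0.2, 32, 128)
    )
    sab2: SABConfig = field(
        default_factory=lambda: SABConfig(128, 0.4, 64, 512)
    )
    head_widths: tuple[int, ...] = (512, 256, 9)
    concat_coords: bool = True  # append centroid xyz to the 2nd block's features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_widths[-1] != 9:
            raise ValueError("head must end in 9 outputs (a 3x3 matrix)")


def toy_config(seed: int = 0) -> NetworkConfig:
    """Small desk-scale configuration for CPU training and tests."""
    return NetworkConfig(
        sab1=SABConfig(128, 0.25, 16, 32, weightnet_width=8),
        sab2=SABConfig(32, 0.5, 16, 128, weightnet_width=8),
        head_widths=(128, 64, 9),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# geometric structure (parameter-free, cached per cloud)


def farthest_point_sample(points: np.ndarray, k: int, start_index: int = 0) -> np.ndarray:
    """Greedy FPS: indices of ``k`` centroids, starting at ``start_index``.

    At each step the point with the largest minimum distance to the selected
    set is added; ties break to the lowest index (argmax returns the first
    maximum). Deterministic.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    selected = np.empty(k, dtype=np.int64)
    selected[0] = start_index
    min_d = np.linalg.norm(points - points[start_index], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(min_d))
        selected[i] = nxt
        min_d = np.minimum(min_d, np.linalg.norm(points - points[nxt], axis=1))
    return selected


def radius_group(
    points: np.ndarray,
    centroid_idx: np.ndarray,
    radius: float,
    max_group_size: int,
) -> np.ndarray:
    """Fixed-size neighbourhoods: (k, max_group_size) indices into ``points``.

    Membership is inclusive (distance <= radius). Oversized neighbourhoods
    keep the nearest points (stable sort, ties to lower index); undersized
    ones are padded by repeating the centroid's own index, so the centroid
    always belongs to its group.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=float)
    groups = np.empty((len(centroid_idx), max_group_size), dtype=np.int64)
    for row, ci in enumerate(centroid_idx):
        d = np.linalg.norm(points - points[ci], axis=1)
        members = np.flatnonzero(d <= radius)
        order = np.argsort(d[members], kind="stable")
        members = members[order][:max_group_size]
        if len(members) < max_group_size:
            pad = np.full(max_group_size - len(members), ci, dtype=np.int64)
            members = np.concatenate([members, pad])
        groups[row] = members
    return groups


def kde_density(points: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel-density estimate at every point, floored at 1e-8."""
    points = np.asarray(points, dtype=float)
    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    rho = np.exp(-sq / (2.0 * bandwidth**2)).mean(axis=1)
    return np.maximum(rho, 1e-8)


@dataclass
class _SABStructure:
    centroid_idx: np.ndarray  # (k,)
    centroids: np.ndarray  # (k, 3)
    groups: np.ndarray  # (k, g) indices into the block's input cloud
    offsets: np.ndarray  # (k, g, 3) member minus centroid
    inv_density: np.ndarray  # (k, g)


def _build_sab_structure(points: np.ndarray, cfg: SABConfig) -> _SABStructure:
    idx = farthest_point_sample(points, min(cfg.n_centroids, len(points)))
    groups = radius_group(points, idx, cfg.radius, cfg.max_group_size)
    centroids = points[idx]
    offsets = points[groups] - centroids[:, None, :]
    # relative density: the KDE normalized by its cloud mean, so the 1/rho
    # correction stays O(1) and the feature scale is well conditioned
    rho = kde_density(points, cfg.density_bandwidth)
    rho = np.maximum(rho / rho.mean(), 1e-8)
    return _SABStructure(idx, centroids, groups, offsets, 1.0 / rho[groups])


# ---------------------------------------------------------------------------
# parameters


def _sab_param_shapes(cfg: SABConfig, in_channels: int) -> dict[str, tuple[int, ...]]:
    wn = cfg.weightnet_width
    return {
        "wn1_w": (3, wn),
        "wn1_b": (wn,),
        "wn2_w": (wn, wn),
        "wn2_b": (wn,),
        "proj_w": (in_channels * wn, cfg.out_channels),
        "proj_b": (cfg.out_channels,),
    }


def param_shapes(config: NetworkConfig) -> dict[str, tuple[int, ...]]:
    """Shapes of every learnable tensor, derivable from the config alone."""
    shapes: dict[str, tuple[int, ...]] = {}
    c2 = config.sab1.out_channels + (3 if config.concat_coords else 0)
    for name, cfg, c_in in (
        ("sab1", config.sab1, 3),
        ("sab2", config.sab2, c2),
    ):
        for k, v in _sab_param_shapes(cfg, c_in).items():
            shapes[f"{name}.{k}"] = v
    widths = (config.sab2.out_channels,) + tuple(config.head_widths)
    for i in range(len(widths) - 1):
        shapes[f"head{i}.w"] = (widths[i], widths[i + 1])
        shapes[f"head{i}.b"] = (widths[i + 1],)
    return shapes


def count_parameters(config: NetworkConfig) -> int:
    """Exact number of learnable scalars for the configuration."""
    return sum(int(np.prod(s)) for s in param_shapes(config).values())


def init_params(config: NetworkConfig) -> dict[str, np.ndarray]:
    """He-style initialization, seeded from the config."""
    rng = np.random.default_rng(config.seed)
    params = {}
    for name, shape in param_shapes(config).items():
        if name.endswith("_b") or name.endswith(".b"):
            params[name] = np.zeros(shape)
        else:
            fan_in = shape[0]
            params[name] = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return params


# ---------------------------------------------------------------------------
# forward / backward


def pointconv(
    offsets: np.ndarray,
    group_features: np.ndarray,
    inv_density: np.ndarray,
    params: dict[str, np.ndarray],
    prefix: str,
):
    """Density-corrected point convolution over rectangular groups.

    offsets (k, g, 3), group_features (k, g, c), inv_density (k, g).
    Returns (output (k, out), cache for backward).
    """
    w1, b1 = params[f"{prefix}.wn1_w"], params[f"{prefix}.wn1_b"]
    w2, b2 = params[f"{prefix}.wn2_w"], params[f"{prefix}.wn2_b"]
    pw, pb = params[f"{prefix}.proj_w"], params[f"{prefix}.proj_b"]
    k, g, c = group_features.shape
    h1 = offsets @ w1 + b1  # (k, g, wn)
    a1 = np.maximum(h1, 0.0)
    w = a1 @ w2 + b2  # (k, g, wn)
    fd = group_features * inv_density[:, :, None]  # (k, g, c)
    M = np.einsum("kgc,kgw->kcw", fd, w).reshape(k, -1)
    pre = M @ pw + pb
    out = np.maximum(pre, 0.0)
    cache = (offsets, h1, a1, w, fd, M, pre, inv_density, (k, g, c), prefix)
    return out, cache


def _pointconv_backward(d_out, cache, params, grads):
    offsets, h1, a1, w, fd, M, pre, inv_density, (k, g, c), prefix = cache
    pw = params[f"{prefix}.proj_w"]
    w2 = params[f"{prefix}.wn2_w"]
    d_pre = d_out * (pre > 0)
    grads[f"{prefix}.proj_w"] += M.T @ d_pre
    grads[f"{prefix}.proj_b"] += d_pre.sum(axis=0)
    dM = (d_pre @ pw.T).reshape(k, c, -1)
    d_fd = np.einsum("kcw,kgw->kgc", dM, w)
    d_w = np.einsum("kcw,kgc->kgw", dM, fd)
    grads[f"{prefix}.wn2_w"] += np.einsum("kgh,kgw->hw", a1, d_w)
    grads[f"{prefix}.wn2_b"] += d_w.sum(axis=(0, 1))
    d_a1 = d_w @ w2.T
    d_h1 = d_a1 * (h1 > 0)
    grads[f"{prefix}.wn1_w"] += np.einsum("kgo,kgh->oh", offsets, d_h1)
    grads[f"{prefix}.wn1_b"] += d_h1.sum(axis=(0, 1))
    return d_fd * inv_density[:, :, None]  # gradient w.r.t. group features


class NHPNet:
    """The full regressor: SAB1 -> SAB2 -> global max pool -> dense head."""

    def __init__(self, config: NetworkConfig, params: dict[str, np.ndarray] | None = None):
        self.config = config
        self.params = init_params(config) if params is None else params

    # -- structure ---------------------------------------------------------
    def build_structure(self, points: np.ndarray):
        """Parameter-free geometric structure for one normalized cloud."""
        s1 = _build_sab_structure(points, self.config.sab1)
        s2 = _build_sab_structure(s1.centroids, self.config.sab2)
        return (s1, s2)

    # -- forward -----------------------------------------------------------
    def forward(self, points: np.ndarray, structure=None, with_cache: bool = False):
        """Raw (non-orthogonal) 3x3 matrix for a normalized point cloud."""
        points = np.asarray(points, dtype=float)
        max_norm = np.linalg.norm(points, axis=1).max()
        if max_norm > 1.0 + 1e-6:
            warnings.warn(
                f"input cloud is not unit-sphere normalized (max norm {max_norm:.3g})",
                stacklevel=2,
            )
        if structure is None:
            structure = self.build_structure(points)
        s1, s2 = structure
        f0 = points  # initial features are the coordinates themselves
        y1, cache1 = pointconv(
            s1.offsets, f0[s1.groups], s1.inv_density, self.params, "sab1"
        )
        f1 = (
            np.concatenate([y1, s1.centroids], axis=1)
            if self.config.concat_coords
            else y1
        )
        y2, cache2 = pointconv(
            s2.offsets, f1[s2.groups], s2.inv_density, self.params, "sab2"
        )
        pooled = y2.max(axis=0)  # global max pool
        argmax = y2.argmax(axis=0)
        acts = [pooled]
        pres = []
        h = pooled
        n_head = len(self.config.head_widths)
        for i in range(n_head):
            pre = h @ self.params[f"head{i}.w"] + self.params[f"head{i}.b"]
            pres.append(pre)
            h = np.maximum(pre, 0.0) if i < n_head - 1 else pre
            acts.append(h)
        raw = h.reshape(3, 3)
        if with_cache:
            cache = (structure, cache1, cache2, y1, y2, argmax, acts, pres)
            return raw, cache
        return raw

    # -- backward ----------------------------------------------------------
    def backward(self, d_raw: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter tensor."""
        structure, cache1, cache2, y1, y2, argmax, acts, pres = cache
        s1, s2 = structure
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d = np.asarray(d_raw, dtype=float).reshape(-1)
        n_head = len(self.config.head_widths)
        for i in reversed(range(n_head)):
            if i < n_head - 1:
                d = d * (pres[i] > 0)
            grads[f"head{i}.w"] += np.outer(acts[i], d)
            grads[f"head{i}.b"] += d
            d = self.params[f"head{i}.w"] @ d
        # global max pool routes the gradient to the argmax centroid per channel
        d_y2 = np.zeros_like(y2)
        d_y2[argmax, np.arange(y2.shape[1])] = d
        d_g2 = _pointconv_backward(d_y2, cache2, self.params, grads)
        c2 = d_g2.shape[-1]
        d_f1 = np.zeros((y1.shape[0], c2))
        np.add.at(d_f1, s2.groups.reshape(-1), d_g2.reshape(-1, c2))
        d_y1 = d_f1[:, : y1.shape[1]]  # coordinate columns carry no parameter grad
        _pointconv_backward(d_y1, cache1, self.params, grads)
        return grads
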