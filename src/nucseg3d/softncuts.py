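"""Radius-limited 3D affinity graph and the differentiable Soft Normalized Cuts loss.

The volume is viewed as a graph whose nodes are voxels. An edge between
voxels u and v carries the weight

    w(u, v) = exp(-(I(u) - I(v))^2 / sigma_I) * exp(-||X(u) - X(v)||^2 / sigma_X)

when the Euclidean distance between their positions is strictly below the
radius r, and 0 otherwise (squared distances are divided by the sigmas, not
their squares). Self-pairs (u = v) carry weight 1 and are included in the
association. The hard normalized-cut objective

    Ncut_K = sum_k cut(A_k, V - A_k) / cut(A_k, V)

is relaxed to soft per-voxel class memberships p_k(u):

    numerator_k   = sum_{u,v} p_k(u) (1 - p_k(v)) w(u, v)
    denominator_k = sum_{u,v} p_k(u) w(u, v)

and the loss is the sum over classes of their ratio. Minimizing it drives
voxels with similar intensity and nearby positions into the same class; for
K classes the loss lies in [0, K], and the uniform assignment scores K - 1.

Intensities are assumed to be remapped to [0, 100] (see
:func:`nucseg3d.io.remap_intensity`): the default intensity scale sigma_I = 1
is calibrated to that range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AffinityConfig", "edge_weight", "neighborhood_offsets", "soft_ncuts_loss", "soft_ncuts_loss_and_grad"]

_EPS = 1e-8


@dataclass(frozen=True)
class AffinityConfig:
    """Hyperparameters of the voxel affinity graph.

    sigma_I : intensity-similarity scale (assumes [0, 100] intensities).
    sigma_X : spatial-proximity scale.
    radius  : strict Euclidean cutoff, in voxels, beyond which edges are 0.
    n_classes : number of soft classes K.
    """

    sigma_I: float = 1.0
    sigma_X: float = 4.0
    radius: float = 2.0
    n_classes: int = 2

    def __post_init__(self):
        if self.sigma_I <= 0 or self.sigma_X <= 0:
            raise ValueError("sigma_I and sigma_X must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def edge_weight(f_u, f_v, x_u, x_v, cfg: AffinityConfig) -> float:
    """Affinity between two voxels given intensities and integer positions."""
    dx = np.asarray(x_u, dtype=float) - np.asarray(x_v, dtype=float)
    d2 = float(np.dot(dx, dx))
    if d2 >= cfg.radius**2:
        return 0.0
    df2 = float(f_u - f_v) ** 2
    return float(np.exp(-df2 / cfg.sigma_I) * np.exp(-d2 / cfg.sigma_X))


def neighborhood_offsets(radius: float) -> list[tuple[int, int, int]]:
    """All nonzero integer offsets with Euclidean norm strictly below radius."""
    m = int(np.ceil(radius))
    offs = []
    for dz in range(-m, m + 1):
        for dy in range(-m, m + 1):
            for dx in range(-m, m + 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if dz * dz + dy * dy + dx * dx < radius**2:
                    offs.append((dz, dy, dx))
    return offs


def _pair_slices(shape, off):
    """Slices (u-region, v-region) such that v = u + off stays in bounds."""
    sl_u, sl_v = [], []
    for dim, d in zip(shape, off):
        lo_u = max(0, -d)
        hi_u = dim - max(0, d)
        sl_u.append(slice(lo_u, hi_u))
        sl_v.append(slice(lo_u + d, hi_u + d))
    return tuple(sl_u), tuple(sl_v)


def _check_inputs(probs, vol, cfg):
    probs = np.asarray(probs, dtype=np.float64)
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {vol.shape}")
    if probs.ndim != 4 or probs.shape[1:] != vol.shape:
        raise ValueError(
            f"probs must have shape (K,) + {vol.shape}, got {probs.shape}"
        )
    if probs.shape[0] != cfg.n_classes:
        raise ValueError(
            f"probs has {probs.shape[0]} classes but config says {cfg.n_classes}"
        )
    return probs, vol


def _neighbor_sums(probs, vol, cfg):
    """S[k](u) = sum_v w(u,v) p_k(v) and W1(u) = sum_v w(u,v), v within radius.

    Self-pairs contribute weight 1. Computed by per-offset shifted products,
    which is algebraically identical to the pairwise double sum restricted by
    the radius cutoff.
    """
    K = probs.shape[0]
    S = probs.copy()  # self-pair: w(u,u) = 1
    W1 = np.ones_like(vol)
    for off in neighborhood_offsets(cfg.radius):
        sl_u, sl_v = _pair_slices(vol.shape, off)
        d2 = sum(d * d for d in off)
        spatial = np.exp(-d2 / cfg.sigma_X)
        di = vol[sl_u] - vol[sl_v]
        w = np.exp(-(di * di) / cfg.sigma_I) * spatial
        W1[sl_u] += w
        for k in range(K):
            S[k][sl_u] += w * probs[k][sl_v]
    return S, W1


def soft_ncuts_loss(probs, vol, cfg: AffinityConfig | None = None) -> float:
    """Soft Normalized Cuts loss of soft class memberships on a volume."""
    cfg = cfg or AffinityConfig()
    probs, vol = _check_inputs(probs, vol, cfg)
    S, W1 = _neighbor_sums(probs, vol, cfg)
    loss = 0.0
    for k in range(probs.shape[0]):
        assoc = float(np.sum(probs[k] * S[k]))
        den = float(np.sum(probs[k] * W1))
        if den < _EPS:
            continue  # empty class: its term is defined as 0
        loss += 1.0 - assoc / den
    return loss


def soft_ncuts_loss_and_grad(probs, vol, cfg: AffinityConfig | None = None):
    """Loss and its analytic gradient with respect to the memberships.

    For class k with association A_k = sum p_k (W p_k), degree D_k =
    sum p_k W1 and term 1 - A_k/D_k, symmetry of w gives

        d/dp_k(u) = -(2 S_k(u) D_k - A_k W1(u)) / D_k^2.
    """
    cfg = cfg or AffinityConfig()
    probs, vol = _check_inputs(probs, vol, cfg)
    S, W1 = _neighbor_sums(probs, vol, cfg)
    grad = np.zeros_like(probs)
    loss = 0.0
    for k in range(probs.shape[0]):
        assoc = float(np.sum(probs[k] * S[k]))
        den = float(np.sum(probs[k] * W1))
        if den < _EPS:
            continue
        loss += 1.0 - assoc / den
        grad[k] = -(2.0 * S[k] * den - assoc * W1) / (den * den)
    return loss, grad
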