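import numpy as np
import pytest

from nucseg3d.softncuts import AffinityConfig
from nucseg3d.synth import SynthConfig, generate_nuclei_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def affinity():
    return AffinityConfig()


@pytest.fixture(scope="session")
def small_nuclei_pair():
    """A 32-cube volume with 15 nuclei and exact labels (session-cached)."""
    cfg = SynthConfig(
        shape=(32, 32, 32),
        n_cells=15,
        radius_range=(2.0, 4.0),
        min_separation=4.0,
        seed=0,
    )
    return generate_nuclei_volume(cfg)


def brute_force_soft_ncuts(probs, vol, cfg):
    """O(N^2) reference for the Soft Normalized Cuts loss.

    Sums over all ordered voxel pairs (self-pairs included) with Euclidean
    distance strictly below the radius; numerator p_k(u)(1-p_k(v))w(u,v),
    denominator p_k(u)w(u,v); a class with ~zero association contributes 0.
    """
    probs = np.asarray(probs, dtype=np.float64)
    vol = np.asarray(vol, dtype=np.float64)
    coords = list(np.ndindex(vol.shape))
    loss = 0.0
    for k in range(probs.shape[0]):
        num = den = 0.0
        for u in coords:
            for v in coords:
                d2 = sum((a - b) ** 2 for a, b in zip(u, v))
                if d2 >= cfg.radius**2:
                    continue
                w = np.exp(-((vol[u] - vol[v]) ** 2) / cfg.sigma_I) * np.exp(-d2 / cfg.sigma_X)
                num += probs[(k, *u)] * (1.0 - probs[(k, *v)]) * w
                den += probs[(k, *u)] * w
        if den >= 1e-8:
            loss += num / den
    return loss


def random_soft_assignment(rng, shape, k=2):
    """Random per-voxel categorical distributions of shape (k, *shape)."""
    p = rng.dirichlet(np.ones(k), size=shape)
    return np.moveaxis(p, -1, 0)
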