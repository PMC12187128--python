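"""Synthetic 3D nuclei volumes with exact instance ground truth.

The generator emulates the statistics the self-supervised objective relies
on: bright, roughly convex nuclei (axis-aligned ellipsoids with a Gaussian
intensity profile peaking at the center) over a darker background, imaged
through a Gaussian point-spread function and corrupted by detector noise.
Optional extras: a smooth background gradient, a brightness halo around each
nucleus, and bright streak artifacts mimicking tissue-clearing defects.

The PSF blur matters for more than realism: the affinity graph of the
segmentation objective uses a sharp intensity-similarity scale (sigma_I = 1
on a [0, 100] range), which presumes that background voxels differ from
their neighbours by little — true of optically blurred microscopy, false of
voxel-independent noise. Labels are the exact pre-blur ellipsoid supports,
created before blur and noise, so the ground truth is exact by
construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io import write_volume

__all__ = ["SynthConfig", "ArtifactSpec", "generate_nuclei_volume", "add_artifact", "make_benchmark_suite"]

_MAX_ATTEMPTS = 10_000


@dataclass
class ArtifactSpec:
    """A bright streak: a cylinder of given axis, radius and added intensity."""

    axis: int = 0  # streak runs along this axis (0=Z)
    center: tuple | None = None  # (two in-plane coords); None = auto placement
    radius: float = 2.0
    amplitude: float = 60.0
    avoid_nuclei: bool = True


@dataclass
class SynthConfig:
    shape: tuple = (64, 64, 64)
    n_cells: int = 15
    radius_range: tuple = (2.0, 6.0)  # semi-axes drawn uniformly, voxels
    cell_intensity_range: tuple = (60.0, 100.0)  # peak brightness
    background_level: float = 5.0
    psf_sigma: float = 1.0  # Gaussian point-spread function, voxels
    noise_sd: float = 0.5  # additive detector noise, post-blur
    noise_model: str = "gaussian"  # or "poisson"
    min_separation: float = 4.0  # centers at least this far apart
    halo: float = 0.0  # brightness-halo amplitude around each nucleus
    background_gradient: float = 0.0  # peak-to-peak smooth gradient amplitude
    artifact: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.radius_range[0] < 1:
            raise ValueError("radii must be >= 1 voxel")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")


def _place_centers(cfg: SynthConfig, rng, margin):
    centers = []
    lo = np.asarray([margin] * 3)
    hi = np.asarray(cfg.shape) - margin - 1
    if np.any(hi < lo):
        raise ValueError(f"volume {cfg.shape} too small for nuclei of radius {margin}")
    for i in range(cfg.n_cells):
        for attempt in range(_MAX_ATTEMPTS):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - p) >= cfg.min_separation for p in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{cfg.n_cells} after {_MAX_ATTEMPTS} attempts; "
                "reduce n_cells or min_separation"
            )
    return centers


def generate_nuclei_volume(cfg: SynthConfig | None = None):
    """Generate one (intensity volume, instance labels) pair.

    Nuclei are rejection-sampled ellipsoids respecting ``min_separation``
    between centers; intensity falls off as a Gaussian of the normalized
    ellipsoidal radius and labels cover the full ellipsoid support. A fixed
    seed reproduces the pair bit for bit.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    vol = np.full(cfg.shape, cfg.background_level, dtype=np.float64)
    labels = np.zeros(cfg.shape, dtype=np.uint16)
    if cfg.background_gradient > 0:
        zz, yy, xx = np.meshgrid(*[np.linspace(0, 1, s) for s in cfg.shape], indexing="ij")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        ramp = direction[0] * zz + direction[1] * yy + direction[2] * xx
        ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-12)
        vol += cfg.background_gradient * ramp
    margin = cfg.radius_range[1]
    centers = _place_centers(cfg, rng, margin)
    grid = np.indices(cfg.shape, dtype=np.float64)
    for i, c in enumerate(centers, start=1):
        semi = rng.uniform(cfg.radius_range[0], cfg.radius_range[1], size=3)
        peak = rng.uniform(*cfg.cell_intensity_range)
        lo = np.maximum(np.floor(c - semi - 2), 0).astype(int)
        hi = np.minimum(np.ceil(c + semi + 3), cfg.shape).astype(int)
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        r2 = sum(((grid[a][box] - c[a]) / semi[a]) ** 2 for a in range(3))
        inside = r2 <= 1.0
        profile = peak * np.exp(-1.5 * r2)
        vol[box] = np.where(inside, np.maximum(vol[box], cfg.background_level + profile), vol[box])
        if cfg.halo > 0:
            shell = (r2 > 1.0) & (r2 <= 2.25)
            vol[box][shell] += cfg.halo * np.exp(-(r2[shell] - 1.0))
        labels[box][inside] = i
    if cfg.artifact is not None:
        vol, _ = add_artifact(vol, labels, cfg.artifact, rng=rng)
    if cfg.psf_sigma > 0:  # optical blur acts on the scene, noise on the detector
        from scipy import ndimage as ndi

        vol = ndi.gaussian_filter(vol, cfg.psf_sigma)
    if cfg.noise_model == "gaussian":
        if cfg.noise_sd > 0:
            vol += rng.normal(0.0, cfg.noise_sd, cfg.shape)
    else:
        vol = rng.poisson(np.maximum(vol, 0.0)).astype(np.float64)
    vol = np.maximum(vol, 0.0)
    return vol.astype(np.float32), labels


def add_artifact(vol: np.ndarray, labels: np.ndarray, spec: ArtifactSpec, rng=None):
    """Add a bright streak to the volume; labels are untouched.

    Returns ``(volume, artifact_mask)`` so tests can exclude the artifact
    region when scoring, mirroring the practice of cropping artifact regions
    out before evaluation. By default the streak is placed away from nuclei.
    """
    rng = rng or np.random.default_rng(0)
    vol = np.asarray(vol, dtype=np.float64).copy()
    labels = np.asarray(labels)
    shape = vol.shape
    plane_axes = [a for a in range(3) if a != spec.axis]
    if spec.center is not None:
        center = np.asarray(spec.center, dtype=float)
        if np.any(center < 0) or np.any(center >= np.asarray([shape[a] for a in plane_axes])):
            raise ValueError(f"artifact center {spec.center} outside volume {shape}")
        centers = [center]
    else:
        centers = []
        for _ in range(_MAX_ATTEMPTS):
            c = rng.uniform([0, 0], [shape[plane_axes[0]], shape[plane_axes[1]]])
            centers = [c]
            if not spec.avoid_nuclei:
                break
            mask = _cylinder_mask(shape, spec.axis, c, spec.radius)
            if not (labels[mask] > 0).any():
                break
        else:
            raise RuntimeError("could not place artifact away from nuclei")
    mask = _cylinder_mask(shape, spec.axis, centers[0], spec.radius)
    vol[mask] += spec.amplitude
    return vol, mask


def _cylinder_mask(shape, axis, center, radius):
    plane_axes = [a for a in range(3) if a != axis]
    grid = np.indices(shape, dtype=np.float64)
    d2 = (grid[plane_axes[0]] - center[0]) ** 2 + (grid[plane_axes[1]] - center[1]) ** 2
    return d2 <= radius**2


def make_benchmark_suite(out_dir, n_volumes: int, cfg: SynthConfig | None = None, seed: int = 0):
    """Write paired volume/label TIFFs plus a JSON manifest.

    Each volume gets its own derived seed recorded in the manifest, so the
    suite can be regenerated byte-identically.
    """
    cfg = cfg or SynthConfig()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_volumes):
        vseed = int(rng.integers(0, 2**31 - 1))
        vcfg = SynthConfig(**{**cfg.__dict__, "seed": vseed})
        vol, labels = generate_nuclei_volume(vcfg)
        vol_path = os.path.join(out_dir, f"volume_{i:03d}.tif")
        lab_path = os.path.join(out_dir, f"labels_{i:03d}.tif")
        write_volume(vol, vol_path)
        write_volume(labels, lab_path)
        entries.append(
            {
                "volume": os.path.basename(vol_path),
                "labels": os.path.basename(lab_path),
                "seed": vseed,
                "n_cells": int(labels.max()),
            }
        )
    manifest = {"seed": seed, "shape": list(cfg.shape), "volumes": entries}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
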