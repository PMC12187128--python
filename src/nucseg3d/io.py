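"""Volume I/O, intensity normalization, patch extraction, and augmentation.

All volumes use axis order (Z, Y, X) with 0-based indexing. Anisotropic voxel
size is ignored throughout: the segmentation objective operates in voxel units.
"""

from __future__ import annotations

import numpy as np
import tifffile

__all__ = [
    "VolumeError",
    "MissingFileError",
    "MultiChannelError",
    "NotAnImageError",
    "read_volume",
    "write_volume",
    "remap_intensity",
    "percentile_clip_normalize",
    "extract_patches",
    "patch_grid",
    "apply_flip_rot",
    "augment",
]


class VolumeError(ValueError):
    """Base error for invalid volume inputs."""


class MissingFileError(VolumeError):
    """The requested file does not exist."""


class MultiChannelError(VolumeError):
    """The file holds multi-channel (e.g. RGB) data; a single channel is required."""


class NotAnImageError(VolumeError):
    """The file could not be parsed as a TIFF image."""


def read_volume(path) -> np.ndarray:
    """Read a single-channel 2D or 3D TIFF as a float (Z, Y, X) volume.

    A 2D image is promoted to shape (1, Y, X). Raises
    :class:`MissingFileError`, :class:`MultiChannelError` or
    :class:`NotAnImageError` on the corresponding failure.
    """
    import os

    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types for bad files
        raise NotAnImageError(f"could not read {path} as TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise MultiChannelError(
            f"{path}: expected single-channel 2D/3D data, got shape {data.shape}"
        )
    # RGB(A) stacks read as (Z, Y, X, S) are caught above; a trailing sample
    # axis of size 3/4 on 2D input appears as ndim == 3 with small last axis
    # and photometric RGB — detect via dtype/shape heuristic from tifffile.
    if data.shape[-1] in (3, 4):
        with tifffile.TiffFile(path) as tf:
            if tf.pages[0].samplesperpixel > 1:
                raise MultiChannelError(f"{path}: multi-sample (RGB) TIFF not supported")
    vol = data.astype(np.float32, copy=False)
    if not np.all(np.isfinite(vol)):
        raise VolumeError(f"{path}: volume contains non-finite values")
    return vol


def _label_dtype(max_label: int):
    if max_label <= np.iinfo(np.uint16).max:
        return np.uint16
    return np.uint32


def write_volume(vol: np.ndarray, path) -> None:
    """Write a 3D volume to a multi-page TIFF.

    Integer (label) volumes are stored as the narrowest unsigned type that
    holds the maximum label (at least uint16 beyond the uint8 range);
    float volumes are stored as float32.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3 or vol.size == 0:
        raise VolumeError(f"expected a non-empty 3D volume, got shape {vol.shape}")
    if np.issubdtype(vol.dtype, np.integer) or vol.dtype == bool:
        if np.any(np.asarray(vol, dtype=np.int64) < 0):
            raise VolumeError("label volumes must be non-negative")
        out = vol.astype(_label_dtype(int(vol.max(initial=0))))
    else:
        out = vol.astype(np.float32)
    tifffile.imwrite(path, out, photometric="minisblack")


def remap_intensity(vol: np.ndarray, lo: float = 0.0, hi: float = 100.0) -> np.ndarray:
    """Affinely remap intensities so min(vol) -> lo and max(vol) -> hi.

    A constant volume maps to all-``lo``. This is the preprocessing the
    self-supervised objective assumes: with the default [0, 100] range an
    intensity-similarity scale of 1 makes the affinity sharply contrast
    sensitive.
    """
    if not hi > lo:
        raise ValueError(f"hi must exceed lo, got lo={lo}, hi={hi}")
    vol = np.asarray(vol, dtype=np.float32)
    if not np.all(np.isfinite(vol)):
        raise VolumeError("remap_intensity requires finite input")
    vmin = float(vol.min())
    vmax = float(vol.max())
    if vmax == vmin:
        return np.full_like(vol, lo)
    return (vol - vmin) * ((hi - lo) / (vmax - vmin)) + lo


def percentile_clip_normalize(
    vol: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0
) -> np.ndarray:
    """Clip intensities to the [p_lo, p_hi] percentile values.

    Percentiles use linear interpolation between order statistics. Values
    inside the band are unchanged.
    """
    if not (0.0 <= p_lo < p_hi <= 100.0):
        raise ValueError(f"need 0 <= p_lo < p_hi <= 100, got {p_lo}, {p_hi}")
    vol = np.asarray(vol, dtype=np.float32)
    lo_val, hi_val = np.percentile(vol, [p_lo, p_hi])
    return np.clip(vol, lo_val, hi_val)


def patch_grid(dim: int, edge: int) -> list[int]:
    """Start offsets of edge-length windows tiling one axis.

    Windows are non-overlapping except the last, which is shifted back to end
    at the boundary when ``dim`` is not a multiple of ``edge``.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    if dim < edge:
        raise ValueError(f"dimension {dim} smaller than patch edge {edge}")
    starts = list(range(0, dim - edge + 1, edge))
    if starts[-1] + edge < dim:
        starts.append(dim - edge)
    return starts


def extract_patches(
    vol: np.ndarray,
    edge: int = 64,
    labels: np.ndarray | None = None,
):
    """Tile a volume (and optional paired labels) into edge**3 patches.

    Returns a list of ``(patch, patch_labels)`` tuples (``patch_labels`` is
    None when no labels are given). The union of patches covers every voxel;
    the final window on each axis is edge-aligned to the boundary.
    """
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise VolumeError(f"expected 3D volume, got shape {vol.shape}")
    if labels is not None and labels.shape != vol.shape:
        raise VolumeError("labels shape must match volume shape")
    out = []
    for z0 in patch_grid(vol.shape[0], edge):
        for y0 in patch_grid(vol.shape[1], edge):
            for x0 in patch_grid(vol.shape[2], edge):
                sl = (slice(z0, z0 + edge), slice(y0, y0 + edge), slice(x0, x0 + edge))
                lab = labels[sl].copy() if labels is not None else None
                out.append((vol[sl].copy(), lab))
    return out


_ROT_PLANES = ((0, 1), (0, 2), (1, 2))


def apply_flip_rot(vol: np.ndarray, flips, plane: int, k: int) -> np.ndarray:
    """Apply axis flips then a k*90-degree rotation in one of the ZY/ZX/YX planes.

    Purely geometric: the multiset of voxel values is preserved exactly.
    """
    out = vol
    for ax, f in enumerate(flips):
        if f:
            out = np.flip(out, axis=ax)
    if k % 4:
        out = np.rot90(out, k=k, axes=_ROT_PLANES[plane])
    return np.ascontiguousarray(out)


def augment(
    vol: np.ndarray,
    labels: np.ndarray | None = None,
    mode: str = "selfsup",
    seed: int | np.random.Generator = 0,
    intensity_shift: float = 0.1,
    affine_scale: float = 0.05,
):
    """Randomly augment a volume (and paired labels).

    ``selfsup`` mode draws only axis flips and 90-degree rotations, so the
    voxel-value histogram is untouched. ``supervised`` mode additionally
    applies a random additive intensity shift (fraction ``intensity_shift``
    of the dynamic range) and a small random affine warp (zoom/shear up to
    ``affine_scale``); labels are warped with nearest-neighbour resampling.
    Geometric transforms are applied identically to volume and labels, and a
    fixed seed reproduces the output bit-for-bit.
    """
    if mode not in ("selfsup", "supervised"):
        raise ValueError(f"unknown augmentation mode: {mode}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flips = rng.random(3) < 0.5
    plane = int(rng.integers(0, 3))
    k = int(rng.integers(0, 4))
    out = apply_flip_rot(np.asarray(vol), flips, plane, k)
    lab = None
    if labels is not None:
        lab = apply_flip_rot(np.asarray(labels), flips, plane, k)
    if mode == "supervised":
        from scipy import ndimage as ndi

        mat = np.eye(3) + rng.uniform(-affine_scale, affine_scale, (3, 3))
        center = (np.asarray(out.shape) - 1) / 2.0
        offset = center - mat @ center
        warped = ndi.affine_transform(out.astype(np.float32), mat, offset=offset, order=1, mode="reflect")
        if lab is not None:
            lab = ndi.affine_transform(lab, mat, offset=offset, order=0, mode="constant")
        rng_span = float(out.max() - out.min())
        warped = warped + rng.uniform(-1, 1) * intensity_shift * rng_span
        out = warped
    return out, lab
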