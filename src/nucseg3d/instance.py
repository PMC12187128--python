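"""From semantic probabilities to instance labels.

Thresholding, three labeling strategies (Voronoi-Otsu, connected components,
distance-transform watershed), and the post-processing operators used to
clean up detections: morphological closing, merging of labels whose shared
border is bright, and volume-based size filtering. Connectivity is fixed at
26 (3D full connectivity) for components, adjacency, and borders, matching
the roughly-convex-object assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu as _skimage_otsu
from skimage.measure import label as _cc_label
from skimage.morphology import ball, local_maxima
from skimage.segmentation import watershed as _watershed

__all__ = [
    "InstanceSegParams",
    "threshold_probabilities",
    "otsu_threshold",
    "voronoi_otsu_label",
    "connected_components_label",
    "watershed_label",
    "morphological_closing",
    "merge_labels_by_border_intensity",
    "filter_by_volume",
    "segment_instances",
]


@dataclass
class InstanceSegParams:
    """Instance segmentation parameters.

    spot_sigma controls seed detection (larger -> fewer seeds), outline_sigma
    the smoothing of the mask outline; both in voxels. The defaults are the
    values used for mesoSPIM-style nuclei.
    """

    method: str = "voronoi_otsu"
    spot_sigma: float = 0.65
    outline_sigma: float = 0.65
    probability_threshold: float = 0.5

    def __post_init__(self):
        if self.method not in ("voronoi_otsu", "connected_components", "watershed"):
            raise ValueError(f"unknown instance method: {self.method}")
        if self.spot_sigma < 0 or self.outline_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")


def threshold_probabilities(probs: np.ndarray, class_index: int, t: float) -> np.ndarray:
    """Binary mask of voxels whose class probability strictly exceeds t."""
    probs = np.asarray(probs)
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if not 0 <= class_index < probs.shape[0]:
        raise IndexError(f"class index {class_index} out of range for {probs.shape[0]} classes")
    return probs[class_index] > t


def otsu_threshold(vol: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold over a 256-bin histogram."""
    vol = np.asarray(vol)
    if float(vol.min()) == float(vol.max()):
        raise ValueError("Otsu threshold is undefined for a constant volume")
    return float(_skimage_otsu(vol.ravel(), nbins=256))


def _gaussian(vol, sigma):
    return ndi.gaussian_filter(np.asarray(vol, dtype=np.float64), sigma) if sigma > 0 else np.asarray(vol, dtype=np.float64)


def voronoi_otsu_label(vol: np.ndarray, spot_sigma: float = 0.65, outline_sigma: float = 0.65) -> np.ndarray:
    """Voronoi-Otsu instance labeling.

    Seeds are the regional maxima of the spot-smoothed volume (one seed per
    connected plateau); the mask is the Otsu threshold of the outline-smoothed
    volume; seeds outside the mask are dropped and mask voxels are partitioned
    among the surviving seeds by Euclidean proximity (a Voronoi tessellation
    restricted to the mask). Separates touching convex objects that a plain
    connected-components pass would fuse.
    """
    vol = np.asarray(vol, dtype=np.float64)
    spot = _gaussian(vol, spot_sigma)
    outline = _gaussian(vol, outline_sigma)
    if float(outline.min()) == float(outline.max()):
        return np.zeros(vol.shape, dtype=np.uint16)
    mask = outline > _skimage_otsu(outline.ravel(), nbins=256)
    maxima = local_maxima(spot, connectivity=3)
    maxima &= mask
    seeds, n_seeds = ndi.label(maxima, structure=np.ones((3, 3, 3), dtype=bool))
    if n_seeds == 0:
        return np.zeros(vol.shape, dtype=np.uint16)
    # Euclidean Voronoi: nearest-seed assignment inside the mask
    _, (iz, iy, ix) = ndi.distance_transform_edt(seeds == 0, return_indices=True)
    labels = seeds[iz, iy, ix]
    labels[~mask] = 0
    return labels.astype(np.uint32 if n_seeds > np.iinfo(np.uint16).max else np.uint16)


def connected_components_label(mask: np.ndarray) -> np.ndarray:
    """Label maximal 26-connected foreground components 1..n."""
    mask = np.asarray(mask).astype(bool)
    return _cc_label(mask, connectivity=3).astype(np.uint32)


def watershed_label(mask: np.ndarray) -> np.ndarray:
    """Distance-transform watershed within a binary mask.

    Seeds are the regional maxima of the interior Euclidean distance map;
    basins are flooded on the negated distance map, restricted to the mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.uint16)
    dist = ndi.distance_transform_edt(mask)
    maxima = local_maxima(dist, connectivity=3) & mask
    seeds, n_seeds = ndi.label(maxima, structure=np.ones((3, 3, 3), dtype=bool))
    if n_seeds == 0:  # degenerate flat mask
        return connected_components_label(mask).astype(np.uint16)
    return _watershed(-dist, markers=seeds, mask=mask).astype(np.uint32)


def morphological_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing (dilation then erosion) with a ball structuring element."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if radius == 0:
        return mask.copy()
    selem = ball(radius)
    # pad so dilation near the border behaves as on an infinite background
    p = radius
    padded = np.pad(mask, p)
    closed = ndi.binary_erosion(ndi.binary_dilation(padded, selem), selem)
    return closed[p:-p, p:-p, p:-p]


def _border_pairs(instances):
    """Mean-intensity accumulator keys: 26-adjacent pairs of distinct labels."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0):
                    offsets.append((dz, dy, dx))
    return offsets


def merge_labels_by_border_intensity(
    instances: np.ndarray, vol: np.ndarray, lo: float = 35.0, hi: float = 100.0
) -> np.ndarray:
    """Merge touching labels whose shared border is bright.

    For every pair of labels with 26-adjacent voxels, the border intensity is
    the mean of the volume over all voxels on both sides of the contact; a
    pair whose border mean lies in [lo, hi] is merged. Merging is transitive
    (union-find) and the result is relabeled compactly. Assumes the volume is
    remapped to [0, 100] so the default bounds [35, 100] single out genuinely
    bright contacts (over-split nuclei) while dim contacts stay separate.
    """
    instances = np.asarray(instances)
    vol = np.asarray(vol, dtype=np.float64)
    if instances.shape != vol.shape:
        raise ValueError("instances and volume shapes differ")
    sums: dict = {}
    counts: dict = {}
    for off in _border_pairs(instances):
        sl_u, sl_v = [], []
        for dim, d in zip(instances.shape, off):
            lo_u = max(0, -d)
            hi_u = dim - max(0, d)
            sl_u.append(slice(lo_u, hi_u))
            sl_v.append(slice(lo_u + d, hi_u + d))
        sl_u, sl_v = tuple(sl_u), tuple(sl_v)
        a, b = instances[sl_u], instances[sl_v]
        touch = (a > 0) & (b > 0) & (a != b)
        if not touch.any():
            continue
        pa, pb = a[touch], b[touch]
        ia, ib = vol[sl_u][touch], vol[sl_v][touch]
        lo_lab = np.minimum(pa, pb)
        hi_lab = np.maximum(pa, pb)
        for la, lb, va, vb in zip(lo_lab, hi_lab, ia, ib):
            key = (int(la), int(lb))
            sums[key] = sums.get(key, 0.0) + va + vb
            counts[key] = counts.get(key, 0) + 2
    # union-find over qualifying pairs
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for key, s in sums.items():
        mean = s / counts[key]
        if lo <= mean <= hi:
            ra, rb = find(key[0]), find(key[1])
            if ra != rb:
                parent[rb] = ra
    out = instances.copy()
    labels = np.unique(instances)
    labels = labels[labels > 0]
    root_of = {int(l): find(int(l)) for l in labels}
    compact: dict = {}
    mapping = np.zeros(int(instances.max()) + 1, dtype=np.int64)
    for l in labels:
        r = root_of[int(l)]
        if r not in compact:
            compact[r] = len(compact) + 1
        mapping[int(l)] = compact[r]
    out = mapping[instances]
    return out.astype(instances.dtype if instances.dtype.kind == "u" else np.uint32)


def filter_by_volume(
    instances: np.ndarray,
    min_voxels: int = 0,
    max_voxels: float = np.inf,
    relabel: bool = False,
) -> np.ndarray:
    """Remove labels whose voxel count falls outside [min_voxels, max_voxels].

    The self-supervised detector has no notion of a cell, so aberrantly small
    or large particles (noise specks, bright artifacts) are filtered by size.
    Survivors keep their identity unless ``relabel`` asks for compact labels.
    """
    if not 0 <= min_voxels < max_voxels:
        raise ValueError("need 0 <= min_voxels < max_voxels")
    instances = np.asarray(instances)
    labels, counts = np.unique(instances, return_counts=True)
    keep = (labels > 0) & (counts >= min_voxels) & (counts <= max_voxels)
    mapping = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int64)
    kept = labels[keep]
    if relabel:
        mapping[kept] = np.arange(1, kept.size + 1)
    else:
        mapping[kept] = kept
    return mapping[instances].astype(instances.dtype)


def segment_instances(
    source: np.ndarray,
    params: InstanceSegParams | None = None,
    *,
    is_probability: bool = False,
    class_index: int = 1,
    closing_radius: int = 0,
    merge_intensity_bounds: tuple | None = None,
    merge_volume: np.ndarray | None = None,
    min_voxels: int = 0,
    max_voxels: float = np.inf,
) -> np.ndarray:
    """Full instance pipeline: threshold -> label -> closing -> merge -> size filter.

    ``source`` is either a raw intensity volume or (with ``is_probability``)
    a (K, Z, Y, X) probability stack thresholded at
    ``params.probability_threshold`` on ``class_index``. Voronoi-Otsu can run
    on either the raw intensities or the thresholded probability channel.
    """
    params = params or InstanceSegParams()
    if is_probability:
        mask = threshold_probabilities(source, class_index, params.probability_threshold)
        work = np.asarray(source[class_index], dtype=np.float64) * mask
    else:
        work = np.asarray(source, dtype=np.float64)
        mask = None
    if closing_radius > 0 and mask is not None:
        mask = morphological_closing(mask, closing_radius)
        work = np.asarray(source[class_index], dtype=np.float64) * mask
    if params.method == "voronoi_otsu":
        labels = voronoi_otsu_label(work, params.spot_sigma, params.outline_sigma)
    elif params.method == "connected_components":
        labels = connected_components_label(mask if mask is not None else work > otsu_threshold(work))
    else:
        labels = watershed_label(mask if mask is not None else work > otsu_threshold(work))
    if merge_intensity_bounds is not None:
        vol_for_merge = merge_volume if merge_volume is not None else work
        labels = merge_labels_by_border_intensity(labels, vol_for_merge, *merge_intensity_bounds)
    if min_voxels > 0 or np.isfinite(max_voxels):
        labels = filter_by_volume(labels, min_voxels, max_voxels)
    return labels
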