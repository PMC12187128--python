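import numpy as np
import pytest
from scipy import ndimage as ndi

from nucseg3d.instance import (
    InstanceSegParams,
    connected_components_label,
    filter_by_volume,
    merge_labels_by_border_intensity,
    morphological_closing,
    otsu_threshold,
    segment_instances,
    threshold_probabilities,
    voronoi_otsu_label,
    watershed_label,
)
from nucseg3d.synth import SynthConfig, generate_nuclei_volume


def _sphere(shape, center, radius):
    grid = np.indices(shape, dtype=float)
    d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


class TestThreshold:
    def test_limits(self, rng):
        probs = np.stack([1 - (p := rng.uniform(size=(4, 4, 4))), p])
        np.testing.assert_array_equal(threshold_probabilities(probs, 1, 0.0), probs[1] > 0)
        assert not threshold_probabilities(probs, 1, 1.0).any()

    def test_monotone_in_threshold(self, rng):
        probs = np.stack([1 - (p := rng.uniform(size=(5, 5, 5))), p])
        m_lo = threshold_probabilities(probs, 1, 0.3)
        m_hi = threshold_probabilities(probs, 1, 0.7)
        assert (m_hi <= m_lo).all()

    def test_class_index_checked(self, rng):
        probs = rng.uniform(size=(2, 3, 3, 3))
        with pytest.raises(IndexError):
            threshold_probabilities(probs, 5, 0.5)


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 100.0
        t = otsu_threshold(vol)
        assert 0.0 < t < 100.0

    def test_matches_exhaustive_search_over_bins(self, rng):
        vol = np.concatenate([rng.normal(20, 5, 400), rng.normal(70, 8, 200)]).reshape(
            (6, 10, 10)
        )
        t = otsu_threshold(vol)
        # brute force: maximize between-class variance over 256 bin edges
        counts, edges = np.histogram(vol, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best_var, best_t = -1.0, None
        n = counts.sum()
        for i in range(1, 256):
            w0, w1 = counts[:i].sum(), counts[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (counts[:i] * centers[:i]).sum() / w0
            mu1 = (counts[i:] * centers[i:]).sum() / w1
            var = w0 / n * w1 / n * (mu0 - mu1) ** 2
            if var > best_var:
                best_var, best_t = var, centers[i - 1]
        assert t == pytest.approx(best_t, abs=(edges[1] - edges[0]))

    def test_affine_equivariance(self, rng):
        vol = rng.uniform(0, 1, (5, 5, 5))
        t = otsu_threshold(vol)
        t2 = otsu_threshold(vol * 50 + 10)
        assert t2 == pytest.approx(t * 50 + 10, rel=1e-6)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((3, 3, 3), 4.0))


class TestVoronoiOtsu:
    def test_two_separated_spheres(self):
        vol = np.full((24, 24, 24), 2.0)
        for c in ((6, 6, 6), (17, 17, 17)):
            vol[_sphere(vol.shape, c, 4)] = 90.0
        vol = ndi.gaussian_filter(vol, 1.0)
        labels = voronoi_otsu_label(vol, 0.65, 0.65)
        assert labels.max() == 2
        assert labels[6, 6, 6] != labels[17, 17, 17]
        assert labels[6, 6, 6] > 0 and labels[17, 17, 17] > 0

    def test_flat_dark_volume_yields_empty_map(self):
        out = voronoi_otsu_label(np.full((8, 8, 8), 3.0), 0.65, 0.65)
        assert out.shape == (8, 8, 8) and not out.any()

    def test_thirty_synthetic_nuclei_recovered(self):
        cfg = SynthConfig(
            shape=(64, 64, 64), n_cells=30, radius_range=(2.0, 4.0), min_separation=10.0, seed=7
        )
        vol, gt = generate_nuclei_volume(cfg)
        labels = voronoi_otsu_label(vol, 0.65, 0.65)
        assert abs(int(labels.max()) - 30) <= 1

    def test_seed_count_nonincreasing_in_spot_sigma(self):
        cfg = SynthConfig(
            shape=(48, 48, 48), n_cells=12, radius_range=(2.0, 4.0), min_separation=9.0, seed=3
        )
        vol, _ = generate_nuclei_volume(cfg)
        counts = [int(voronoi_otsu_label(vol, s, 0.65).max()) for s in (0.65, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_labels_inside_foreground_only(self):
        cfg = SynthConfig(shape=(32, 32, 32), n_cells=5, min_separation=9.0, radius_range=(2, 4), seed=1)
        vol, _ = generate_nuclei_volume(cfg)
        labels = voronoi_otsu_label(vol, 0.65, 0.65)
        # labeled voxels must be brighter on average than background voxels
        assert vol[labels > 0].mean() > vol[labels == 0].mean()


class TestComponentsAndWatershed:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[:2, :2, :2] = True
        mask[5:7, 5:7, 5:7] = True
        assert connected_components_label(mask).max() == 2

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        assert connected_components_label(mask).max() == 1

    def test_component_count_matches_flood_fill(self, rng):
        def flood_count(mask):
            seen = np.zeros_like(mask)
            count = 0
            offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                    if (a, b, c) != (0, 0, 0)]
            for start in zip(*np.nonzero(mask)):
                if seen[start]:
                    continue
                count += 1
                stack = [start]
                seen[start] = True
                while stack:
                    z, y, x = stack.pop()
                    for dz, dy, dx in offs:
                        p = (z + dz, y + dy, x + dx)
                        if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not seen[p]:
                            seen[p] = True
                            stack.append(p)
            return count

        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.2
            assert connected_components_label(mask).max() == flood_count(mask)

    def test_watershed_single_sphere_one_label(self):
        mask = _sphere((16, 16, 16), (8, 8, 8), 5)
        labels = watershed_label(mask)
        assert labels.max() == 1

    def test_watershed_splits_dumbbell(self):
        mask = _sphere((30, 16, 16), (9, 8, 8), 5) | _sphere((30, 16, 16), (20, 8, 8), 5)
        labels = watershed_label(mask)
        assert labels.max() == 2
        assert labels[9, 8, 8] != labels[20, 8, 8]

    def test_watershed_partitions_mask_exactly(self, rng):
        mask = ndi.binary_dilation(rng.random((12, 12, 12)) < 0.05, iterations=2)
        labels = watershed_label(mask)
        np.testing.assert_array_equal(labels > 0, mask)


class TestClosing:
    def test_radius_zero_identity(self, rng):
        mask = rng.random((6, 6, 6)) < 0.3
        np.testing.assert_array_equal(morphological_closing(mask, 0), mask)

    def test_fills_one_voxel_hole(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        mask[6, 6, 6] = False
        closed = morphological_closing(mask, 2)
        assert closed[6, 6, 6]

    def test_matches_dilate_then_erode(self, rng):
        from skimage.morphology import ball

        mask = rng.random((10, 10, 10)) < 0.15
        r = 2
        padded = np.pad(mask, r)
        expected = ndi.binary_erosion(ndi.binary_dilation(padded, ball(r)), ball(r))[
            r:-r, r:-r, r:-r
        ]
        np.testing.assert_array_equal(morphological_closing(mask, r), expected)


class TestBorderMerge:
    @staticmethod
    def _touching_pair(border_value):
        instances = np.zeros((4, 4, 8), dtype=np.uint16)
        instances[:, :, :4] = 1
        instances[:, :, 4:] = 2
        vol = np.zeros((4, 4, 8))
        vol[:, :, 3:5] = border_value  # both sides of the contact
        return instances, vol

    def test_bright_border_merges(self):
        instances, vol = self._touching_pair(50.0)
        merged = merge_labels_by_border_intensity(instances, vol, 35, 100)
        assert len(np.unique(merged)) - (0 in merged) == 1

    def test_dim_border_stays_split(self):
        instances, vol = self._touching_pair(10.0)
        merged = merge_labels_by_border_intensity(instances, vol, 35, 100)
        assert set(np.unique(merged)) == {1, 2}

    def test_non_touching_never_merge(self):
        instances = np.zeros((4, 4, 9), dtype=np.uint16)
        instances[:, :, :3] = 1
        instances[:, :, 6:] = 2
        vol = np.full((4, 4, 9), 99.0)
        merged = merge_labels_by_border_intensity(instances, vol, 35, 100)
        assert merged.max() == 2

    def test_transitive_merging_and_support_preserved(self):
        instances = np.zeros((2, 2, 9), dtype=np.uint16)
        instances[:, :, :3] = 1
        instances[:, :, 3:6] = 2
        instances[:, :, 6:] = 3
        vol = np.full((2, 2, 9), 60.0)
        merged = merge_labels_by_border_intensity(instances, vol, 35, 100)
        assert len(np.unique(merged)) == 1  # all one label, no background
        np.testing.assert_array_equal(merged > 0, instances > 0)

    def test_never_increases_label_count(self, rng):
        instances = connected_components_label(rng.random((8, 8, 8)) < 0.3)
        vol = rng.uniform(0, 100, (8, 8, 8))
        merged = merge_labels_by_border_intensity(instances, vol, 35, 100)
        assert len(np.unique(merged)) <= len(np.unique(instances))
        np.testing.assert_array_equal(merged > 0, instances > 0)


class TestSizeFilter:
    def test_identity_with_open_bounds(self, rng):
        instances = connected_components_label(rng.random((8, 8, 8)) < 0.2)
        np.testing.assert_array_equal(filter_by_volume(instances), instances)

    def test_small_speck_removed(self):
        instances = np.zeros((8, 8, 8), dtype=np.uint16)
        instances[0, 0, :5] = 1  # 5-voxel speck
        instances[4:7, 4:7, 4:7] = 2
        out = filter_by_volume(instances, min_voxels=10)
        assert 1 not in out and 2 in out

    def test_survivor_count_matches_histogram(self, rng):
        instances = connected_components_label(rng.random((12, 12, 12)) < 0.25)
        lo, hi = 3, 40
        out = filter_by_volume(instances, lo, hi, relabel=True)
        labels, counts = np.unique(instances[instances > 0], return_counts=True)
        expected = int(((counts >= lo) & (counts <= hi)).sum())
        assert int(out.max()) == expected

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_by_volume(np.zeros((2, 2, 2), np.uint16), 5, 5)


class TestPipeline:
    def test_probability_entry_point(self, rng):
        fg = np.zeros((16, 16, 16))
        fg[_sphere(fg.shape, (8, 8, 8), 4)] = 0.95
        probs = np.stack([1 - fg, fg])
        labels = segment_instances(
            probs, InstanceSegParams(probability_threshold=0.5), is_probability=True
        )
        assert labels.max() == 1

    def test_labels_subset_of_mask(self, rng):
        fg = rng.uniform(size=(12, 12, 12)) * 0.6
        fg[_sphere(fg.shape, (6, 6, 6), 3)] = 0.9
        probs = np.stack([1 - fg, fg])
        params = InstanceSegParams(method="connected_components", probability_threshold=0.7)
        labels = segment_instances(probs, params, is_probability=True)
        assert not labels[~(fg > 0.7)].any()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            InstanceSegParams(method="magic")
        with pytest.raises(ValueError):
            InstanceSegParams(spot_sigma=-1)
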