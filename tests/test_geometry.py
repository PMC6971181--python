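import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lggspat import (
    EmptyMaskError,
    GridMismatchError,
    LabelVolume,
    UnsupportedGeometryError,
    bounding_box_world,
    connected_components,
    mask_centroid_world,
    mask_volume_ml,
    min_surface_distance,
    overlap_volume_ml,
)
from lggspat.geometry import world_axis_spacing

from .conftest import brute_min_distance, digitized_sphere, make_affine, random_mask, vol_from_indices


class TestMaskVolume:
    def test_empty_mask_has_zero_volume(self):
        assert mask_volume_ml(vol_from_indices([])) == 0.0

    @pytest.mark.parametrize(
        "n_voxels,spacing,expected_ml",
        [(1000, (1, 1, 1), 1.0), (100, (0.5, 0.5, 2.0), 0.05), (10, (1, 1, 1), 0.01)],
    )
    def test_volume_is_count_times_voxel_volume(self, n_voxels, spacing, expected_ml, rng):
        shape = (12, 12, 12)
        flat = rng.choice(np.prod(shape), size=n_voxels, replace=False)
        idx = np.column_stack(np.unravel_index(flat, shape))
        vol = vol_from_indices(idx, shape=shape, spacing=spacing)
        assert mask_volume_ml(vol) == pytest.approx(expected_ml)

    def test_digitized_sphere_close_to_analytic(self):
        sphere = digitized_sphere(10.0)
        analytic = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0
        assert mask_volume_ml(sphere) == pytest.approx(analytic, rel=0.05)
        # volume definition agrees with directly counting in-radius centers
        assert mask_volume_ml(sphere) == sphere.n_foreground / 1000.0


class TestCentroid:
    def test_single_voxel_identity_affine(self):
        vol = vol_from_indices([(2, 3, 4)])
        assert np.allclose(mask_centroid_world(vol), (2, 3, 4))

    def test_two_voxels_average(self):
        vol = vol_from_indices([(0, 0, 0), (2, 0, 0)])
        assert np.allclose(mask_centroid_world(vol), (1, 0, 0))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            mask_centroid_world(vol_from_indices([]))


class TestConnectedComponents:
    def test_corner_adjacency_depends_on_connectivity(self):
        vol = vol_from_indices([(0, 0, 0), (1, 1, 1)])
        assert connected_components(vol, 26).n == 1
        assert connected_components(vol, 6).n == 2

    def test_empty_mask_has_no_components(self):
        assert connected_components(vol_from_indices([])).n == 0

    def test_sizes_sorted_and_sum_to_total_volume(self, rng):
        vol = random_mask(rng, shape=(20, 20, 20), max_voxels=200)
        comps = connected_components(vol)
        assert np.all(np.diff(comps.sizes_ml) <= 0)
        assert np.all(comps.sizes_ml > 0)
        assert comps.sizes_ml.sum() == pytest.approx(mask_volume_ml(vol))
        union = np.zeros(vol.shape, dtype=bool)
        for i in range(1, comps.n + 1):
            union |= comps.mask(i).voxels
        assert np.array_equal(union, vol.voxels)

    def test_equal_size_tie_broken_by_first_voxel(self):
        # two single-voxel components; the lexicographically smaller index wins rank 1
        vol = vol_from_indices([(5, 0, 0), (0, 5, 0)])
        comps = connected_components(vol, 6)
        assert comps.mask(1).voxels[0, 5, 0]
        assert comps.mask(2).voxels[5, 0, 0]


class TestMinSurfaceDistance:
    def test_overlapping_masks_have_zero_distance(self):
        a = vol_from_indices([(1, 1, 1), (2, 2, 2)])
        b = vol_from_indices([(2, 2, 2), (3, 3, 3)])
        assert min_surface_distance(a, b) == 0.0

    def test_pythagorean_distance(self):
        a = vol_from_indices([(0, 0, 0)])
        b = vol_from_indices([(3, 4, 0)])
        assert min_surface_distance(a, b) == 5.0

    def test_anisotropic_spacing_respected(self):
        # index-adjacent along an axis with 3 mm slices
        a = vol_from_indices([(0, 0, 0)], spacing=(1, 1, 3))
        b = vol_from_indices([(0, 0, 1)], spacing=(1, 1, 3))
        assert min_surface_distance(a, b) == 3.0

    def test_empty_mask_rejected(self):
        a = vol_from_indices([(0, 0, 0)])
        with pytest.raises(EmptyMaskError):
            min_surface_distance(a, vol_from_indices([]))

    def test_grid_mismatch_rejected(self):
        a = vol_from_indices([(0, 0, 0)], spacing=(1, 1, 1))
        b = vol_from_indices([(0, 0, 0)], spacing=(2, 1, 1))
        with pytest.raises(GridMismatchError):
            min_surface_distance(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_edt_equals_bruteforce_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        spacing = tuple(rng.choice([0.5, 1.0, 2.0, 3.0], size=3))
        origin = tuple(rng.integers(-8, 8, size=3) * 0.25)
        a = random_mask(rng, shape=(14, 10, 12), spacing=spacing, origin=origin, max_voxels=60)
        b = random_mask(rng, shape=(14, 10, 12), spacing=spacing, origin=origin, max_voxels=60)
        d = min_surface_distance(a, b)
        assert d == brute_min_distance(a, b)
        assert d == min_surface_distance(b, a)
        # overlap iff zero distance
        assert (overlap_volume_ml(a, b) > 0) == (d == 0.0)


class TestOverlapVolume:
    def test_disjoint_masks(self):
        a = vol_from_indices([(0, 0, 0)])
        b = vol_from_indices([(5, 5, 5)])
        assert overlap_volume_ml(a, b) == 0.0

    def test_subset_overlap_is_subset_volume(self, rng):
        b = random_mask(rng, max_voxels=40)
        idx = b.foreground_indices()[: max(1, b.n_foreground // 2)]
        a = b.with_voxels(vol_from_indices(idx, shape=b.shape).voxels)
        assert overlap_volume_ml(a, b) == pytest.approx(mask_volume_ml(a))

    def test_ten_voxel_intersection_at_1mm(self):
        a = vol_from_indices([(i, 0, 0) for i in range(10)] + [(0, 5, 0)], shape=(12, 12, 12))
        b = vol_from_indices([(i, 0, 0) for i in range(12)], shape=(12, 12, 12))
        assert overlap_volume_ml(a, b) == pytest.approx(0.01)


class TestBoundingBox:
    def test_single_voxel_box(self):
        box = bounding_box_world(vol_from_indices([(1, 2, 3)]))
        assert np.allclose(box.lo, (1, 2, 3)) and np.allclose(box.hi, (1, 2, 3))

    def test_two_voxel_box(self):
        box = bounding_box_world(vol_from_indices([(0, 0, 0), (4, 2, 0)]))
        assert np.allclose(box.lo, (0, 0, 0)) and np.allclose(box.hi, (4, 2, 0))

    def test_oblique_affine_rejected(self):
        theta = np.deg2rad(10)
        aff = np.eye(4)
        aff[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        vol = LabelVolume(np.ones((4, 4, 4), dtype=bool), aff)
        with pytest.raises(UnsupportedGeometryError):
            bounding_box_world(vol)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            bounding_box_world(vol_from_indices([]))

    def test_world_axis_spacing_follows_permutation(self):
        # voxel axis 0 maps to world z, axis 2 to world x
        aff = np.zeros((4, 4))
        aff[2, 0], aff[1, 1], aff[0, 2], aff[3, 3] = 3.0, 1.0, 0.5, 1.0
        vol = LabelVolume(np.ones((4, 4, 4), dtype=bool), aff)
        assert np.allclose(world_axis_spacing(vol), (0.5, 1.0, 3.0))


class TestInvariances:
    def test_joint_translation_leaves_outputs_unchanged(self, rng):
        for _ in range(5):
            a = random_mask(rng, spacing=(1, 2, 0.5), max_voxels=40)
            b = random_mask(rng, spacing=(1, 2, 0.5), max_voxels=40)
            shift = rng.integers(-10, 10, size=3) * 0.5
            at = LabelVolume(a.voxels, make_affine((1, 2, 0.5), shift))
            bt = LabelVolume(b.voxels, make_affine((1, 2, 0.5), shift))
            assert min_surface_distance(a, b) == min_surface_distance(at, bt)
            assert mask_volume_ml(a) == mask_volume_ml(at)
            assert np.allclose(
                mask_centroid_world(a) - mask_centroid_world(b),
                mask_centroid_world(at) - mask_centroid_world(bt),
            )

    def test_joint_axis_permutation_leaves_world_outputs_unchanged(self, rng):
        a = random_mask(rng, spacing=(1, 2, 0.5), max_voxels=40)
        b = random_mask(rng, spacing=(1, 2, 0.5), max_voxels=40)
        perm = (2, 0, 1)
        aff = a.affine[:, list(perm) + [3]]
        ap = LabelVolume(np.transpose(a.voxels, perm), aff)
        bp = LabelVolume(np.transpose(b.voxels, perm), aff)
        assert min_surface_distance(ap, bp) == min_surface_distance(a, b)
        assert mask_volume_ml(ap) == mask_volume_ml(a)
        assert np.allclose(mask_centroid_world(ap), mask_centroid_world(a))
        box, boxp = bounding_box_world(a), bounding_box_world(ap)
        assert np.allclose(box.lo, boxp.lo) and np.allclose(box.hi, boxp.hi)
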