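"""Background VOI construction, margin geometry and TBR segmentation.

Oracles are brute-force per-voxel evaluations of the definitions on small
grids: ball membership by enumerating voxel-centre distances, margins by
all-pairs distance enumeration, and the segmentation by literal evaluation
of threshold, margin and exclusion for every voxel.
"""

import numpy as np
import pytest

from contour_agree.io_masks import BinaryMask, ImageVolume
from contour_agree.pet_segmentation import (
    DegenerateVOIError,
    TBRSegmentationParams,
    background_mean,
    build_background_voi,
    margin_region,
    segment_tbr,
)

from conftest import make_grid, mask_from_array


def constant_pet(grid, value=1.0):
    return ImageVolume(
        data=np.full(grid.shape, float(value)),
        spacing=grid.spacing,
        affine=grid.affine,
        modality_label="FET-PET",
    )


def six_centers(point):
    return np.tile(np.asarray(point, float), (6, 1))


def brute_force_margin(reference, margin_mm):
    """All-pairs voxel-centre distance enumeration."""
    coords = reference.grid.world_coordinates().reshape(-1, 3)
    ref_pts = coords[reference.data.reshape(-1)]
    out = np.zeros(len(coords), dtype=bool)
    for i, c in enumerate(coords):
        d = np.sqrt(((ref_pts - c) ** 2).sum(axis=1))
        out[i] = d.min() <= margin_mm
    return out.reshape(reference.grid.shape)


class TestBackgroundVOI:
    def test_constant_image_mean(self):
        grid = make_grid((24, 24, 24), (2.0, 2.0, 2.0))
        pet = constant_pet(grid, 3.7)
        voi = build_background_voi(pet, six_centers((0.0, 0.0, 0.0)))
        assert voi.mean_uptake == pytest.approx(3.7)
        assert background_mean(voi, pet) == pytest.approx(3.7)

    def test_ball_rasterization_matches_enumeration(self):
        grid = make_grid((30, 30, 30), (1.0, 1.0, 1.0))
        pet = constant_pet(grid)
        voi = build_background_voi(pet, six_centers((0.0, 0.0, 0.0)),
                                   roi_diameter_mm=20.0)
        coords = grid.world_coordinates().reshape(-1, 3)
        expected = int((np.sqrt((coords**2).sum(axis=1)) <= 10.0).sum())
        assert voi.mask.voxel_count == expected

    def test_union_is_idempotent_for_coincident_centers(self):
        grid = make_grid((30, 30, 30))
        pet = constant_pet(grid)
        voi = build_background_voi(pet, six_centers((1.0, -2.0, 0.0)))
        # all six balls coincide: the union equals one ball
        single = grid.world_coordinates()
        d = np.sqrt(((single - np.array([1.0, -2.0, 0.0])) ** 2).sum(axis=-1))
        np.testing.assert_array_equal(voi.mask.data, d <= 10.0)

    def test_center_outside_grid_rejected(self):
        grid = make_grid((16, 16, 16))
        with pytest.raises(ValueError, match="outside"):
            build_background_voi(constant_pet(grid), six_centers((500.0, 0.0, 0.0)))

    def test_out_of_range_diameter_warns(self):
        grid = make_grid((30, 30, 30))
        with pytest.warns(UserWarning, match="diameter"):
            build_background_voi(constant_pet(grid), six_centers((0, 0, 0)),
                                 roi_diameter_mm=10.0)

    def test_mean_ignores_values_outside_voi(self, rng):
        grid = make_grid((24, 24, 24), (2.0, 2.0, 2.0))
        pet = constant_pet(grid, 2.0)
        voi = build_background_voi(pet, six_centers((0, 0, 0)))
        outside = ~voi.mask.data
        data = pet.data.copy()
        data[outside] = rng.random(outside.sum()) * 100
        hot = ImageVolume(data, grid.spacing, grid.affine)
        assert background_mean(voi, hot) == pytest.approx(2.0)


class TestMarginRegion:
    def test_zero_margin_is_identity(self, rng, grid16):
        ref = mask_from_array(rng.random(grid16.shape) < 0.1, grid16)
        out = margin_region(ref, 0.0)
        np.testing.assert_array_equal(out.data, ref.data)

    def test_single_voxel_euclidean_ball(self):
        grid = make_grid((9, 9, 9))
        data = np.zeros(grid.shape, bool)
        data[4, 4, 4] = True
        out = margin_region(mask_from_array(data, grid), 2.0)
        # integer points with squared norm <= 4: brute-force count is 33
        assert out.voxel_count == 33

    def test_anisotropic_spacing_respected(self):
        grid = make_grid((9, 9, 9), (1.0, 1.0, 3.0))
        data = np.zeros(grid.shape, bool)
        data[4, 4, 4] = True
        out = margin_region(mask_from_array(data, grid), 2.0)
        assert not out.data[4, 4, 2]  # 6 mm away along z
        assert not out.data[4, 4, 6]
        assert out.data[4, 2, 4]            # 2 mm away along y

    @pytest.mark.parametrize("margin", [0.0, 1.5, 4.0, 10.0])
    def test_matches_brute_force_enumeration(self, rng, margin):
        grid = make_grid((10, 11, 9), (1.0, 2.0, 1.5))
        ref = mask_from_array(rng.random(grid.shape) < 0.05, grid)
        if ref.is_empty:
            pytest.skip("draw produced empty reference")
        out = margin_region(ref, margin)
        np.testing.assert_array_equal(out.data, brute_force_margin(ref, margin))

    def test_reference_subset_of_result(self, rng, grid16):
        ref = mask_from_array(rng.random(grid16.shape) < 0.2, grid16)
        out = margin_region(ref, 3.0)
        assert np.all(out.data[ref.data])

    def test_empty_reference_rejected(self, grid16):
        with pytest.raises(ValueError, match="empty"):
            margin_region(mask_from_array(np.zeros(grid16.shape, bool), grid16), 5.0)


def make_phantom_pet(grid, background=1.0, tumor_value=2.0, tumor_slices=None):
    data = np.full(grid.shape, float(background))
    if tumor_slices is not None:
        data[tumor_slices] = tumor_value
    return ImageVolume(data, grid.spacing, grid.affine, "FET-PET")


class TestSegmentTBR:
    def setup_method(self):
        self.grid = make_grid((32, 32, 32), (2.0, 2.0, 2.0))
        self.tumor = np.zeros(self.grid.shape, bool)
        self.tumor[12:18, 12:18, 12:18] = True

    def clean_voi(self, pet):
        return build_background_voi(pet, six_centers((-20.0, -20.0, -20.0)))

    def test_noiseless_phantom_recovers_tumor_exactly(self):
        pet = make_phantom_pet(self.grid, 1.0, 2.0, self.tumor)
        params = TBRSegmentationParams(
            reference_mask=mask_from_array(self.tumor, self.grid)
        )
        out = segment_tbr(pet, self.clean_voi(pet), params)
        np.testing.assert_array_equal(out.data, self.tumor)

    def test_uniform_image_segments_nothing(self):
        pet = make_phantom_pet(self.grid, 1.0)
        params = TBRSegmentationParams(
            reference_mask=mask_from_array(self.tumor, self.grid)
        )
        assert segment_tbr(pet, self.clean_voi(pet), params).is_empty

    def test_hot_lesion_beyond_margin_excluded(self):
        data = np.full(self.grid.shape, 1.0)
        data[28:30, 28:30, 28:30] = 5.0  # > 30 mm from the reference cube
        pet = ImageVolume(data, self.grid.spacing, self.grid.affine)
        reference = np.zeros(self.grid.shape, bool)
        reference[2:5, 2:5, 2:5] = True
        params = TBRSegmentationParams(
            reference_mask=mask_from_array(reference, self.grid), margin_mm=30.0
        )
        assert segment_tbr(pet, self.clean_voi(pet), params).is_empty

    def test_exclusion_mask_always_removed(self):
        pet = make_phantom_pet(self.grid, 1.0, 10.0, self.tumor)
        excl = np.zeros(self.grid.shape, bool)
        excl[12:15, 12:18, 12:18] = True
        params = TBRSegmentationParams(
            reference_mask=mask_from_array(self.tumor, self.grid),
            exclusion_mask=mask_from_array(excl, self.grid),
        )
        out = segment_tbr(pet, self.clean_voi(pet), params)
        assert not (out.data & excl).any()
        np.testing.assert_array_equal(out.data, self.tumor & ~excl)

    def test_threshold_monotonicity(self, rng):
        data = 1.0 + rng.random(self.grid.shape)
        pet = ImageVolume(data, self.grid.spacing, self.grid.affine)
        ref = mask_from_array(self.tumor, self.grid)
        voi = self.clean_voi(pet)
        prev = None
        for thr in (1.2, 1.4, 1.6, 1.8):
            out = segment_tbr(
                pet, voi, TBRSegmentationParams(reference_mask=ref, tbr_threshold=thr)
            )
            if prev is not None:
                assert np.all(prev.data | ~out.data)  # out subset of prev
            prev = out

    def test_margin_monotonicity(self, rng):
        data = 1.0 + rng.random(self.grid.shape)
        pet = ImageVolume(data, self.grid.spacing, self.grid.affine)
        ref = mask_from_array(self.tumor, self.grid)
        voi = self.clean_voi(pet)
        small = segment_tbr(
            pet, voi, TBRSegmentationParams(reference_mask=ref, margin_mm=5.0)
        )
        large = segment_tbr(
            pet, voi, TBRSegmentationParams(reference_mask=ref, margin_mm=25.0)
        )
        assert np.all(large.data[small.data])

    def test_scale_invariance(self, rng):
        data = 1.0 + rng.random(self.grid.shape)
        pet = ImageVolume(data, self.grid.spacing, self.grid.affine)
        scaled = ImageVolume(data * 37.5, self.grid.spacing, self.grid.affine)
        ref = mask_from_array(self.tumor, self.grid)
        out1 = segment_tbr(
            pet, self.clean_voi(pet), TBRSegmentationParams(reference_mask=ref)
        )
        out2 = segment_tbr(
            scaled, self.clean_voi(scaled), TBRSegmentationParams(reference_mask=ref)
        )
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_matches_brute_force_definition(self, rng):
        """Literal per-voxel evaluation of threshold, margin and exclusion."""
        grid = make_grid((14, 12, 10), (2.0, 1.0, 3.0))
        data = 0.5 + rng.random(grid.shape) * 2.0
        pet = ImageVolume(data, grid.spacing, grid.affine)
        ref = mask_from_array(rng.random(grid.shape) < 0.05, grid)
        excl = mask_from_array(rng.random(grid.shape) < 0.1, grid)
        voi = build_background_voi(pet, six_centers((0.0, 0.0, 0.0)))
        params = TBRSegmentationParams(
            reference_mask=ref, tbr_threshold=1.3, margin_mm=6.0, exclusion_mask=excl
        )
        out = segment_tbr(pet, voi, params)

        bg = float(data[voi.mask.data].mean())
        margin = brute_force_margin(ref, 6.0)
        expected = (data / bg >= 1.3) & margin & ~excl.data
        np.testing.assert_array_equal(out.data, expected)

    def test_largest_component_filter(self):
        data = np.full(self.grid.shape, 1.0)
        data[12:18, 12:18, 12:18] = 3.0   # 216 voxels
        data[20:22, 20:22, 20:22] = 3.0   # 8 voxels, separate island
        pet = ImageVolume(data, self.grid.spacing, self.grid.affine)
        ref = mask_from_array(self.tumor, self.grid)
        out = segment_tbr(
            pet,
            self.clean_voi(pet),
            TBRSegmentationParams(reference_mask=ref, keep_largest_component=True),
        )
        assert out.voxel_count == 216

    def test_nonpositive_background_rejected(self):
        pet = make_phantom_pet(self.grid, 1.0, 2.0, self.tumor)
        voi = self.clean_voi(pet)
        bad = type(voi)(
            roi_centers=voi.roi_centers,
            roi_diameter_mm=voi.roi_diameter_mm,
            mask=voi.mask,
            mean_uptake=0.0,
        )
        with pytest.raises(ValueError, match="background"):
            segment_tbr(
                pet, bad,
                TBRSegmentationParams(reference_mask=mask_from_array(self.tumor, self.grid)),
            )

    def test_empty_voi_mean_rejected(self):
        grid = make_grid((16, 16, 16))
        pet = constant_pet(grid)
        voi = build_background_voi(pet, six_centers((0, 0, 0)))
        empty = type(voi)(
            roi_centers=voi.roi_centers,
            roi_diameter_mm=voi.roi_diameter_mm,
            mask=mask_from_array(np.zeros(grid.shape, bool), grid),
            mean_uptake=1.0,
        )
        with pytest.raises(DegenerateVOIError):
            background_mean(empty, pet)
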