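import numpy as np
import pytest

from petrad.core import Volume
from petrad.segmentation import (
    MASK_LABELS,
    dice,
    lesion_suvmax,
    make_mask_set,
    threshold_contour,
)
from petrad.synthetic import PhantomSpec, generate_phantom


def _volume_from_row(row, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(row, dtype=float).reshape(1, 1, -1), spacing)


class TestSuvmax:
    def test_constant_field(self, make_volume):
        vol = make_volume(np.full((3, 3, 3), 10.0))
        assert lesion_suvmax(vol, np.ones((3, 3, 3), bool)) == 10.0

    def test_max_under_mask(self):
        vol = _volume_from_row([3, 7, 5])
        mask = np.ones((1, 1, 3), bool)
        assert lesion_suvmax(vol, mask) == 7.0

    def test_noise_free_phantom_matches_spec(self, smooth_phantom):
        spec, vol, mask = smooth_phantom
        assert lesion_suvmax(vol, mask) == pytest.approx(spec.suv_max)

    def test_empty_seed_errors(self, make_volume):
        vol = make_volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            lesion_suvmax(vol, np.zeros((2, 2, 2), bool))


class TestThresholdContour:
    def test_hand_profile(self):
        # cutoff 0.45 * 10 = 4.5 keeps the {5, 10, 6} plateau
        vol = _volume_from_row([1, 2, 5, 10, 6, 2, 1])
        seed = np.zeros((1, 1, 7), bool)
        seed[0, 0, 3] = True
        mask = threshold_contour(vol, seed, 0.45)
        np.testing.assert_array_equal(mask[0, 0], [0, 0, 1, 1, 1, 0, 0])

    def test_fraction_40_cutoff_is_closed(self):
        # SUVmax 10 -> inclusion cutoff 4.0; the comparison is closed (>=)
        vol = _volume_from_row([3.99, 4.0, 10.0])
        seed = np.ones((1, 1, 3), bool)
        mask = threshold_contour(vol, seed, 0.40)
        np.testing.assert_array_equal(mask[0, 0], [0, 1, 1])

    def test_uniform_lesion_keeps_connected_component(self, make_volume):
        vals = np.zeros((5, 5, 5))
        vals[1:4, 1:4, 1:4] = 8.0
        vol = make_volume(vals)
        seed = vals > 0
        for fraction in (0.35, 0.5, 0.9):
            mask = threshold_contour(vol, seed, fraction)
            np.testing.assert_array_equal(mask, seed)

    def test_monotone_in_fraction(self, smooth_phantom):
        _, vol, seed = smooth_phantom
        sizes = [
            threshold_contour(vol, seed, f).sum()
            for f in (0.2, 0.35, 0.40, 0.45, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_fraction(self, smooth_phantom):
        _, vol, seed = smooth_phantom
        with pytest.raises(ValueError):
            threshold_contour(vol, seed, 1.5)

    def test_unreachable_threshold_names_fraction(self, make_volume):
        # with negative intensities fraction * SUVmax can exceed every value
        vol = _volume_from_row([-10.0, -10.0, -10.0])
        seed = np.ones((1, 1, 3), bool)
        with pytest.raises(ValueError, match="0.45"):
            threshold_contour(vol, seed, 0.45)

    def test_picks_component_touching_seed(self, make_volume):
        vals = np.zeros((1, 1, 9))
        vals[0, 0, :3] = 10.0  # large far component
        vals[0, 0, 7:] = 9.0  # small component under the seed
        vol = make_volume(vals)
        seed = np.zeros((1, 1, 9), bool)
        seed[0, 0, 8] = True
        mask = threshold_contour(vol, seed, 0.5)
        assert mask[0, 0, 8] and mask[0, 0, 7] and not mask[0, 0, 0]


class TestMaskSet:
    def test_five_labels_and_nesting(self, smooth_phantom):
        _, vol, mask = smooth_phantom
        ms = make_mask_set(vol, mask, true_mask=mask, surrogate_seed=0)
        assert set(ms.variants) == set(MASK_LABELS)
        assert np.all(ms["suv45"] <= ms["suv40"])
        assert np.all(ms["suv40"] <= ms["suv35"])
        counts = ms.counts()
        assert counts["suv45"] <= counts["suv40"] <= counts["suv35"]

    def test_ct_perception_is_truth(self, smooth_phantom):
        _, vol, mask = smooth_phantom
        ms = make_mask_set(vol, mask, true_mask=mask)
        np.testing.assert_array_equal(ms["ct_perception"], mask)

    def test_pet_perception_deterministic(self, smooth_phantom):
        _, vol, mask = smooth_phantom
        a = make_mask_set(vol, mask, true_mask=mask, surrogate_seed=5)
        b = make_mask_set(vol, mask, true_mask=mask, surrogate_seed=5)
        c = make_mask_set(vol, mask, true_mask=mask, surrogate_seed=6)
        np.testing.assert_array_equal(a["pet_perception"], b["pet_perception"])
        assert (a["pet_perception"] != c["pet_perception"]).any()

    def test_grid_carried(self, smooth_phantom):
        _, vol, mask = smooth_phantom
        ms = make_mask_set(vol, mask, true_mask=mask)
        assert ms.spacing_mm == vol.spacing_mm
        assert ms.origin_mm == vol.origin_mm

    def test_dice_relations_on_nested_masks(self, smooth_phantom):
        _, vol, mask = smooth_phantom
        ms = make_mask_set(vol, mask, true_mask=mask)
        d_40_35 = dice(ms["suv40"], ms["suv35"])
        d_40_45 = dice(ms["suv40"], ms["suv45"])
        d_35_45 = dice(ms["suv35"], ms["suv45"])
        for d in (d_40_35, d_40_45, d_35_45):
            assert 0 < d <= 1
        assert d_40_35 >= d_35_45
        assert d_40_45 >= d_35_45

    def test_ball_radius_matches_profile_inversion(self):
        # profile 1 - 0.5 (r/R)^2 crosses 0.4 at r = R sqrt(1.2) > R, so use a
        # steeper falloff: 1 - 0.9 (r/R)^2 = 0.4 at r = R sqrt(2/3)
        spec = PhantomSpec(
            grid_shape=(30, 30, 30), spacing_mm=(2.0, 2.0, 2.0),
            lesion_radius_mm=20.0, suv_max=10.0, background_suv=0.2,
            heterogeneity_sd=0.0, noise_sd=0.0, radial_falloff=0.9, seed=0,
        )
        vol, mask = generate_phantom(spec)
        suv40 = threshold_contour(vol, mask, 0.40)
        expected_r = 20.0 * np.sqrt((1 - 0.4) / 0.9)
        coords = np.argwhere(suv40) * 2.0
        center = np.asarray(spec.lesion_center_mm)
        radii = np.linalg.norm(coords - center, axis=1)
        assert radii.max() <= expected_r + 2.0  # within one voxel
        assert radii.max() >= expected_r - 2.0
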