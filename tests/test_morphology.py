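"""Segmentation, pixel morphometry and thousand-grain-weight arithmetic."""

import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from seednir import (
    Hypercube,
    SceneSpec,
    compute_morphology,
    nearest_band,
    percent_increase,
    segment_seeds,
    select_segmentation_band,
    tgw_from_samples,
)
from seednir.exceptions import SeedNIRError


class TestBandSelection:
    def test_exact_grid_point(self):
        wl = np.array([1000.0, 1100.0, 1200.0])
        assert nearest_band(wl, 1100.0) == 1

    def test_midpoint_tie_goes_to_lower_band(self):
        wl = np.array([1000.0, 1100.0])
        assert nearest_band(wl, 1050.0) == 0

    def test_default_target_matches_exhaustive_search(self, default_wavelengths):
        idx = nearest_band(default_wavelengths, 1139.26)
        brute = min(
            range(default_wavelengths.size),
            key=lambda i: abs(default_wavelengths[i] - 1139.26),
        )
        assert idx == brute

    def test_select_band_returns_that_image(self, default_wavelengths):
        data = np.arange(2 * 2 * 256, dtype=float).reshape(2, 2, 256)
        cube = Hypercube(data, default_wavelengths)
        img = select_segmentation_band(cube, 1139.26)
        np.testing.assert_array_equal(img, data[:, :, nearest_band(default_wavelengths, 1139.26)])


class TestSegmentation:
    def test_constant_image_yields_no_objects(self):
        assert segment_seeds(np.full((20, 20), 0.3)) == []

    def test_recovers_planted_masks_exactly(self, clean_scene, clean_reflectance, clean_seeds):
        *_, truth = clean_scene
        assert len(clean_seeds) == len(truth.table)
        recovered = np.zeros_like(truth.label_raster)
        for seed in clean_seeds:
            rr, cc = seed.full_indices()
            recovered[rr, cc] = 1
        np.testing.assert_array_equal(recovered > 0, truth.label_raster > 0)

    def test_merged_ellipses_become_one_object(self):
        """Known failure mode: dilation-bridged seeds segment as one object."""
        img = np.zeros((30, 40))
        img[10:16, 5:15] = 1.0
        img[10:16, 16:26] = 1.0
        merged = binary_dilation(img > 0, np.ones((3, 3)))
        objs = segment_seeds(np.where(merged, 1.0, 0.0), min_area=10)
        assert len(objs) == 1


class TestMorphometry:
    @pytest.mark.parametrize(
        "mask,area,perimeter",
        [
            (np.ones((3, 3), bool), 9, 8),  # hand count: 8 contour + 1 interior
            (np.ones((1, 1), bool), 1, 1),
            (np.ones((1, 9), bool), 9, 9),
        ],
        ids=["3x3-square", "single-pixel", "1x9-bar"],
    )
    def test_area_and_perimeter_hand_counts(self, mask, area, perimeter):
        m = compute_morphology(mask)
        assert m.area_px == area
        assert m.perimeter_px == perimeter

    def test_bar_axes_from_brute_force_moments(self):
        mask = np.ones((1, 9), bool)
        m = compute_morphology(mask)
        # brute-force second central moments with the unit-square pixel model
        cols = np.arange(9)
        var = ((cols - cols.mean()) ** 2).mean() + 1 / 12
        assert m.length_px == pytest.approx(4 * np.sqrt(var))
        assert m.length_px > m.width_px > 0
        assert abs(m.orientation_rad) < 1e-12  # major axis along columns

    def test_translation_invariance_and_rotation_equivariance(self):
        base = np.zeros((20, 20), bool)
        base[5:9, 3:14] = True
        m0 = compute_morphology(base)
        shifted = np.roll(base, (4, 2), axis=(0, 1))
        m1 = compute_morphology(shifted)
        assert (m0.area_px, m0.perimeter_px) == (m1.area_px, m1.perimeter_px)
        assert m0.length_px == pytest.approx(m1.length_px)
        rot = np.rot90(base)
        m2 = compute_morphology(rot)
        assert (m2.area_px, m2.perimeter_px) == (m0.area_px, m0.perimeter_px)
        assert m2.length_px == pytest.approx(m0.length_px)
        assert m2.width_px == pytest.approx(m0.width_px)

    def test_recovered_axes_match_planted_ellipses(self, clean_scene, clean_seeds):
        *_, truth = clean_scene
        table = truth.table.set_index("seed_id")
        for seed in clean_seeds:
            # map the segmented object back to its planted seed via centroid
            d = (table["centroid_row"] - seed.centroid[0]) ** 2 + (
                table["centroid_col"] - seed.centroid[1]
            ) ** 2
            planted = table.loc[d.idxmin()]
            assert seed.area_px == planted["area"]
            assert seed.length_px == pytest.approx(planted["length"], abs=2.0)
            assert seed.width_px == pytest.approx(planted["width"], abs=2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(SeedNIRError):
            compute_morphology(np.zeros((3, 3), bool))


class TestTGW:
    def test_constant_samples_match_reported_scale(self):
        assert tgw_from_samples([2.456] * 5).tgw_g == pytest.approx(24.56)

    def test_unit_masses(self):
        assert tgw_from_samples([1, 1, 1, 1, 1]).tgw_g == 10.0

    def test_arithmetic_mean_times_ten(self):
        assert tgw_from_samples([2.40, 2.45, 2.50, 2.55, 2.60]).tgw_g == pytest.approx(25.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(SeedNIRError):
            tgw_from_samples([2.4, -1.0])


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "mutant,wt,expected",
        [(25.99, 24.56, 5.8), (26.25, 25.66, 2.3), (17.0, 17.0, 0.0)],
    )
    def test_one_decimal_report(self, mutant, wt, expected):
        assert percent_increase(mutant, wt) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(SeedNIRError):
            percent_increase(25.0, 0.0)
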