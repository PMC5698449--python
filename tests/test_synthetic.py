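"""Synthetic scene generator: spectral landmarks, scene structure, determinism."""

import numpy as np
import pytest

from seednir import (
    SceneSpec,
    calibrate,
    generate_scene,
    generate_spectral_dataset,
    make_base_spectrum,
    mean_spectrum,
    offset_for_bayes_accuracy,
    segment_seeds,
    select_segmentation_band,
)
from seednir.exceptions import InvalidSpecError, PlacementError
from seednir.synthetic import PEAK_NM, VALLEY1_NM, VALLEY2_NM


class TestBaseSpectrum:
    def test_peak_near_landmark(self, default_wavelengths):
        curve = make_base_spectrum(SceneSpec()).reflectance
        window = (default_wavelengths >= 1050) & (default_wavelengths <= 1180)
        peak_wl = default_wavelengths[window][np.argmax(curve[window])]
        assert abs(peak_wl - PEAK_NM) <= 15.0

    def test_valleys_found_by_exhaustive_scan(self, default_wavelengths):
        """Brute-force local-minimum scan of the discrete curve."""
        curve = make_base_spectrum(SceneSpec()).reflectance
        minima_wl = [
            default_wavelengths[i]
            for i in range(1, curve.size - 1)
            if curve[i] < curve[i - 1] and curve[i] < curve[i + 1]
        ]
        for target in (VALLEY1_NM, VALLEY2_NM):
            assert any(abs(w - target) <= 15.0 for w in minima_wl)

    def test_zero_amplitudes_give_sloped_baseline_only(self):
        spec = SceneSpec(bump_amplitudes=(0.0, 0.0, 0.0))
        curve = make_base_spectrum(spec).reflectance
        # residual against its own linear trend is zero: no features added
        fitted = np.polyval(np.polyfit(spec.wavelengths, curve, 1), spec.wavelengths)
        np.testing.assert_allclose(curve, fitted, atol=1e-10)

    def test_values_in_unit_interval(self):
        curve = make_base_spectrum(SceneSpec()).reflectance
        assert curve.min() > 0.0 and curve.max() < 1.0

    def test_short_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            SceneSpec(n_bands=1)


class TestGenerateScene:
    def test_truth_table_counts(self, clean_scene):
        *_, truth = clean_scene
        assert len(truth.table) == 6
        assert (truth.table["class"].value_counts() == 3).all()

    def test_zero_noise_roundtrip_recovers_base_spectrum(self, clean_spec, clean_reflectance, clean_seeds):
        rho, _ = clean_reflectance
        base = make_base_spectrum(clean_spec).reflectance
        for seed in clean_seeds:
            np.testing.assert_allclose(mean_spectrum(rho, seed), base, atol=1e-10)

    def test_seeds_are_disjoint(self, clean_scene):
        *_, truth = clean_scene
        areas = truth.table["area"].sum()
        assert (truth.label_raster > 0).sum() == areas  # no overlapping ids

    def test_mutant_area_exceeds_wt_at_scale(self):
        """Monte-Carlo over the planted shape distributions (200 seeds/class)."""
        spec = SceneSpec(n_seeds_per_class=(200, 200), n_bands=4, rng_seed=5)
        *_, truth = generate_scene(spec)
        by_class = truth.table.groupby("class")["area"].mean()
        assert by_class[2] > by_class[1]

    def test_placement_error_when_image_too_small(self):
        spec = SceneSpec(n_seeds_per_class=(50, 50), image_height=30, image_width=30, n_bands=4)
        with pytest.raises(PlacementError):
            generate_scene(spec)

    def test_determinism(self):
        spec = SceneSpec(n_seeds_per_class=(4, 4), n_bands=16, rng_seed=77)
        a = generate_scene(spec)
        b = generate_scene(spec)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[3].label_raster, b[3].label_raster)
        assert a[3].table.equals(b[3].table)

    def test_mean_reflectance_ratio_matches_class_offset(self):
        """Planted mutant/WT ratio equals class_offset within Monte-Carlo error."""
        spec = SceneSpec(n_seeds_per_class=(200, 200), n_bands=8, class_offset=1.05, rng_seed=9)
        raw, dark, white, truth = generate_scene(spec)
        rho = calibrate(raw, dark, white)
        cls = truth.table.set_index("seed_id")["class"]
        means = {1: [], 2: []}
        for sid in truth.table["seed_id"]:
            px = rho.data[truth.label_raster == sid]
            means[int(cls[sid])].append(px.mean())
        ratio = np.mean(means[2]) / np.mean(means[1])
        # scatter SD 0.02 over 200 seeds -> SE of the ratio ~ 0.002
        assert ratio == pytest.approx(1.05, abs=0.01)


class TestSpectralDataset:
    def test_row_count_matches_study_sample_size(self):
        ds = generate_spectral_dataset(SceneSpec(rng_seed=1), n_per_class=330)
        assert ds.n_samples == 660
        assert (ds.y == 1).sum() == 330 and (ds.y == 2).sum() == 330

    def test_noise_free_rows_identical_within_class(self):
        spec = SceneSpec(noise_sd=0.0, scatter_sd=0.0, rng_seed=2)
        ds = generate_spectral_dataset(spec, n_per_class=5)
        assert np.ptp(ds.X[ds.y == 1], axis=0).max() == 0.0
        assert np.ptp(ds.X[ds.y == 2], axis=0).max() == 0.0

    def test_bit_identical_under_same_seed(self):
        spec = SceneSpec(rng_seed=42)
        a = generate_spectral_dataset(spec, 20)
        b = generate_spectral_dataset(spec, 20)
        assert a.X.tobytes() == b.X.tobytes()

    def test_offset_restricted_to_band_subset(self):
        planted = np.arange(40, 50)
        spec = SceneSpec(
            noise_sd=0.0, scatter_sd=0.0, class_offset=1.5,
            offset_band_indices=planted, rng_seed=3,
        )
        ds = generate_spectral_dataset(spec, 2)
        ratio = ds.X[ds.y == 2][0] / ds.X[ds.y == 1][0]
        np.testing.assert_allclose(ratio[planted], 1.5)
        mask = np.ones(ds.n_bands, bool)
        mask[planted] = False
        np.testing.assert_allclose(ratio[mask], 1.0)


class TestBayesOffsetCalibration:
    def test_closed_form_matches_simulation(self):
        """Simulated optimal-rule accuracy agrees with the target."""
        sd = 0.02
        off = offset_for_bayes_accuracy(0.95, sd)
        rng = np.random.default_rng(0)
        n = 200_000
        wt = np.exp(rng.normal(0.0, sd, n))
        mut = off * np.exp(rng.normal(0.0, sd, n))
        thr = np.sqrt(off)  # midpoint in log space
        acc = 0.5 * ((wt < thr).mean() + (mut >= thr).mean())
        assert acc == pytest.approx(0.95, abs=0.005)

    def test_rejects_out_of_range_targets(self):
        with pytest.raises(ValueError):
            offset_for_bayes_accuracy(0.4, 0.02)
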