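"""Mean-spectrum extraction, wavelet denoising and dataset assembly."""

import numpy as np
import pytest

from seednir import (
    Hypercube,
    SceneSpec,
    SpectralDataset,
    build_dataset,
    make_base_spectrum,
    mean_spectrum,
    wavelet_denoise,
)
from seednir.exceptions import SeedNIRError, ShapeMismatchError
from seednir.morphology import SeedObject, compute_morphology


def seed_from_mask(mask, offset=(0, 0), object_id=1):
    m = compute_morphology(mask)
    rr, cc = np.nonzero(mask)
    return SeedObject(
        object_id=object_id,
        mask=mask,
        offset=offset,
        area_px=m.area_px,
        perimeter_px=m.perimeter_px,
        length_px=m.length_px,
        width_px=m.width_px,
        centroid=(offset[0] + rr.mean(), offset[1] + cc.mean()),
    )


class TestMeanSpectrum:
    def test_uniform_pixels_return_shared_spectrum(self):
        wl = np.array([1.0, 2.0, 3.0])
        s = np.array([0.2, 0.5, 0.4])
        cube = Hypercube(np.broadcast_to(s, (4, 4, 3)).copy(), wl)
        seed = seed_from_mask(np.ones((2, 2), bool), offset=(1, 1))
        np.testing.assert_array_equal(mean_spectrum(cube, seed), s)

    def test_two_pixel_average(self):
        wl = np.array([1.0, 2.0])
        cube = Hypercube(np.zeros((1, 2, 2)), wl)
        cube.data[0, 0] = [0.2, 0.4]
        cube.data[0, 1] = [0.6, 0.8]
        seed = seed_from_mask(np.ones((1, 2), bool))
        np.testing.assert_allclose(mean_spectrum(cube, seed), [0.4, 0.6])

    def test_zero_noise_seed_reproduces_scaled_base(self, clean_spec, clean_reflectance, clean_seeds):
        rho, _ = clean_reflectance
        base = make_base_spectrum(clean_spec).reflectance
        # unit offset, zero scatter: every seed is exactly the base curve
        np.testing.assert_allclose(mean_spectrum(rho, clean_seeds[0]), base, atol=1e-10)

    def test_out_of_bounds_mask_rejected(self):
        cube = Hypercube(np.zeros((3, 3, 2)), np.array([1.0, 2.0]))
        seed = seed_from_mask(np.ones((2, 2), bool), offset=(2, 2))
        with pytest.raises(SeedNIRError):
            mean_spectrum(cube, seed)


class TestWaveletDenoise:
    def test_constant_spectrum_unchanged(self):
        s = np.full(256, 0.42)
        np.testing.assert_allclose(wavelet_denoise(s), s, atol=1e-8)

    def test_reduces_white_noise_variance(self, rng):
        noise = rng.standard_normal(256)
        assert wavelet_denoise(noise).var() < noise.var()

    def test_improves_mse_on_noisy_base_spectrum(self):
        """Monte-Carlo at 20 dB SNR over 100 replicates."""
        clean = make_base_spectrum(SceneSpec()).reflectance
        sigma = np.sqrt(np.mean(clean**2) / 100.0)  # 20 dB
        rng = np.random.default_rng(202)
        wins = 0
        for _ in range(100):
            noisy = clean + rng.normal(0, sigma, clean.size)
            mse_before = np.mean((noisy - clean) ** 2)
            mse_after = np.mean((wavelet_denoise(noisy) - clean) ** 2)
            wins += mse_after < mse_before
        assert wins >= 95

    def test_near_idempotent_on_smooth_curve(self):
        clean = make_base_spectrum(SceneSpec()).reflectance
        out = wavelet_denoise(clean)
        rms_change = np.sqrt(np.mean((out - clean) ** 2)) / np.sqrt(np.mean(clean**2))
        assert rms_change < 0.01

    def test_too_short_spectrum_names_minimum(self):
        with pytest.raises(SeedNIRError, match=r"at least \d+"):
            wavelet_denoise(np.zeros(32))


class TestBuildDataset:
    def make_scene_cube(self):
        wl = np.linspace(900, 1700, 160)
        cube = Hypercube(np.full((20, 30, 160), 0.1), wl)
        seeds, labels = [], []
        for i, (r, c) in enumerate([(2, 2), (2, 12), (2, 22), (12, 2), (12, 12), (12, 22)]):
            mask = np.ones((4, 4), bool)
            cube.data[r : r + 4, c : c + 4, :] = 0.3 + 0.05 * i
            seeds.append(seed_from_mask(mask, offset=(r, c), object_id=i + 1))
            labels.append(1 if i < 3 else 2)
        return cube, seeds, labels

    def test_assembly_shape_and_labels(self):
        cube, seeds, labels = self.make_scene_cube()
        ds = build_dataset(cube, seeds, labels, denoise=False)
        assert ds.X.shape == (6, 160)
        np.testing.assert_array_equal(ds.y, labels)

    def test_rows_equal_raw_means_when_denoise_off(self):
        cube, seeds, labels = self.make_scene_cube()
        ds = build_dataset(cube, seeds, labels, denoise=False)
        for row, seed in enumerate(seeds):
            np.testing.assert_array_equal(ds.X[row], mean_spectrum(cube, seed))

    def test_permutation_equivariance(self):
        cube, seeds, labels = self.make_scene_cube()
        ds = build_dataset(cube, seeds, labels, denoise=False)
        perm = [3, 0, 5, 1, 4, 2]
        ds2 = build_dataset(
            cube, [seeds[i] for i in perm], [labels[i] for i in perm], denoise=False
        )
        # rows are object_id ordered, so shuffling the input changes nothing
        np.testing.assert_array_equal(ds.X, ds2.X)
        np.testing.assert_array_equal(ds.y, ds2.y)

    def test_label_count_mismatch(self):
        cube, seeds, labels = self.make_scene_cube()
        with pytest.raises(ShapeMismatchError):
            build_dataset(cube, seeds, labels[:-1])

    def test_csv_round_trip(self, tmp_path):
        cube, seeds, labels = self.make_scene_cube()
        ds = build_dataset(cube, seeds, labels, denoise=False, variety="huaidao-1")
        ds.to_csv(tmp_path / "ds.csv")
        back = SpectralDataset.from_csv(tmp_path / "ds.csv")
        np.testing.assert_allclose(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)
        assert back.meta.get("variety") == "huaidao-1"
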