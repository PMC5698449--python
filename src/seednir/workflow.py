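"""End-to-end scene workflow: acquisition model through labelled dataset.

Glue used by the CLI, the acceptance script and the tests: run the imaging
chain (generate or load a scene, calibrate, segment, extract, denoise) and
hand back everything downstream stages need, with seed labels recovered from
the scene's ground-truth raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import Hypercube, calibrate
from .exceptions import SeedNIRError
from .morphology import SeedObject, segment_seeds, select_segmentation_band
from .spectra import SpectralDataset, build_dataset
from .synthetic import USABLE_RANGE_NM, SceneSpec, SceneTruth, generate_scene

__all__ = [
    "ScenePipelineResult",
    "labels_from_truth",
    "process_scene",
    "run_synthetic_scene",
    "discrimination_trial",
    "band_recovery_trial",
    "DISCRIMINATIVE_WAVELENGTHS_NM",
]

# Landmark wavelengths used as planted discriminative features in recovery
# studies: the husk reflectance peak plus C-H overtone / O-H stretch bands.
DISCRIMINATIVE_WAVELENGTHS_NM = (1122.81, 1314.72, 1402.42, 1581.51)


@dataclass
class ScenePipelineResult:
    """Everything the imaging half of the pipeline produces for one scene."""

    reflectance: Hypercube
    seeds: list[SeedObject]
    labels: np.ndarray  # class per segmented seed (1=WT, 2=mutant)
    dataset: SpectralDataset
    truth: SceneTruth | None = None

    def truth_by_object_id(self) -> dict[int, int]:
        return {int(s.object_id): int(lab) for s, lab in zip(self.seeds, self.labels)}


def labels_from_truth(seeds: list[SeedObject], truth: SceneTruth) -> np.ndarray:
    """True class of each segmented seed, by majority vote over its pixels."""
    class_of = dict(zip(truth.table["seed_id"].astype(int), truth.table["class"].astype(int)))
    labels = np.empty(len(seeds), dtype=int)
    for i, seed in enumerate(seeds):
        rr, cc = seed.full_indices()
        ids = truth.label_raster[rr, cc]
        ids = ids[ids > 0]
        if ids.size == 0:
            raise SeedNIRError(
                f"segmented object {seed.object_id} overlaps no planted seed"
            )
        vals, counts = np.unique(ids, return_counts=True)
        labels[i] = class_of[int(vals[np.argmax(counts)])]
    return labels


def process_scene(
    raw: Hypercube,
    dark: Hypercube,
    white: Hypercube,
    truth: SceneTruth | None = None,
    *,
    denoise: bool = True,
    crop: tuple[float, float] | None = USABLE_RANGE_NM,
    labels=None,
    variety: str | None = None,
) -> ScenePipelineResult:
    """Calibrate, segment, extract and assemble the labelled dataset.

    Labels come either from ``truth`` (majority vote against the ground-truth
    raster) or from an explicit per-seed ``labels`` array.
    """
    rho = calibrate(raw, dark, white)
    seeds = segment_seeds(select_segmentation_band(rho))
    if labels is None:
        if truth is None:
            raise SeedNIRError("need either a truth raster or explicit labels")
        labels = labels_from_truth(seeds, truth)
    labels = np.asarray(labels, dtype=int)
    ds = build_dataset(rho, seeds, labels, denoise=denoise, crop=crop, variety=variety)
    return ScenePipelineResult(
        reflectance=rho, seeds=seeds, labels=labels, dataset=ds, truth=truth
    )


def run_synthetic_scene(spec: SceneSpec, **kwargs) -> ScenePipelineResult:
    """Generate a scene from ``spec`` and run :func:`process_scene` on it."""
    raw, dark, white, truth = generate_scene(spec)
    return process_scene(raw, dark, white, truth, **kwargs)


def discrimination_trial(
    rng_seed: int,
    *,
    n_per_class: int = 330,
    bayes_accuracy: float = 0.95,
    scatter_sd: float = 0.02,
    bands: str = "spa",
    classifier: str = "svm",
):
    """One full-pipeline discrimination run on a synthetic acquisition.

    Generates a scene at the study's per-variety scale (default 330 seeds per
    class) with the class offset set so the optimal single-seed classifier
    would reach ``bayes_accuracy``, runs
    calibrate -> segment -> extract -> denoise -> Kennard-Stone 2:1 ->
    band selection -> classifier, and returns the fitted results object.
    """
    from .model import SeedDiscrimination
    from .synthetic import offset_for_bayes_accuracy

    spec = SceneSpec(
        n_seeds_per_class=(n_per_class, n_per_class),
        class_offset=offset_for_bayes_accuracy(bayes_accuracy, scatter_sd),
        scatter_sd=scatter_sd,
        rng_seed=rng_seed,
    )
    scene = run_synthetic_scene(spec)
    return SeedDiscrimination.from_dataset(scene.dataset).fit(
        bands=bands, classifier=classifier, crop=None, denoise=False, seed=rng_seed
    ), scene


def band_recovery_trial(
    rng_seed: int,
    *,
    n_per_class: int = 330,
    bayes_accuracy: float = 0.95,
    scatter_sd: float = 0.02,
    window_bands: int = 3,
):
    """Plant the class offset on known band windows and measure SPA recovery.

    The mutant offset is restricted to ``window_bands``-wide windows around
    :data:`DISCRIMINATIVE_WAVELENGTHS_NM`; a planted feature counts as
    recovered when any SPA-selected wavelength falls inside its window.
    Returns ``(recovered_fraction, results)``.
    """
    from .cube import nearest_band
    from .model import SeedDiscrimination
    from .synthetic import generate_spectral_dataset, offset_for_bayes_accuracy

    wl = SceneSpec().wavelengths
    centers = [nearest_band(wl, c) for c in DISCRIMINATIVE_WAVELENGTHS_NM]
    planted = sorted(
        {i for c in centers for i in range(c - window_bands, c + window_bands + 1)}
    )
    spec = SceneSpec(
        class_offset=offset_for_bayes_accuracy(bayes_accuracy, scatter_sd),
        scatter_sd=scatter_sd,
        offset_band_indices=np.asarray(planted),
        rng_seed=rng_seed,
    )
    ds = generate_spectral_dataset(spec, n_per_class).crop(*USABLE_RANGE_NM)
    res = SeedDiscrimination.from_dataset(ds).fit(
        bands="spa", classifier="svm", crop=None, denoise=False, seed=rng_seed
    )
    step = wl[1] - wl[0]
    tol = step * (window_bands + 0.5)
    recovered = sum(
        any(abs(w - c) <= tol for w in res.selected_wavelengths_nm)
        for c in DISCRIMINATIVE_WAVELENGTHS_NM
    )
    return recovered / len(DISCRIMINATIVE_WAVELENGTHS_NM), res
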