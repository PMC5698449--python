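"""Synthetic NIR hyperspectral scenes of two-class rice seed populations.

The generator emulates the statistical structure a push-broom NIR imaging
line produces for trays of rice seeds from a wild-type acceptor line and a
gene-edited mutant population:

* a 256-channel wavelength axis spanning 874.41-1733.91 nm (uniform grid);
* a smooth seed reflectance curve with a peak near 1122.81 nm and valleys
  near 1200.19 and 1483.46 nm (second-overtone C-H and first-overtone N-H
  features of the husk);
* mutant seeds uniformly brighter than wild type by a multiplicative class
  offset, and slightly larger in area/perimeter/length with unchanged width;
* per-seed multiplicative scatter (log-normal) and additive per-pixel sensor
  noise, inflated outside the usable 975-1646 nm window to mimic detector
  roll-off at the spectral edges.

Scenes come with dark/white reference frames and a ground-truth table so the
whole downstream pipeline (calibration, segmentation, morphometry, spectral
extraction, band selection, classification, mapping) is testable end to end
without any real acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.special import ndtri
from scipy.stats import truncnorm

from .cube import Hypercube, reference_frame
from .exceptions import InvalidSpecError, PlacementError

__all__ = [
    "ShapeStats",
    "SceneSpec",
    "BaseSpectrum",
    "SceneTruth",
    "make_base_spectrum",
    "generate_scene",
    "generate_spectral_dataset",
    "offset_for_bayes_accuracy",
    "truth_to_csv",
]

# Shape statistics (pixel units, mean/SD) for the huaidao-1 acceptor line and
# its mutant: area, perimeter, major-axis length, minor-axis width.  The
# mutant is larger in area/perimeter/length; width is unchanged within noise.
WT_SHAPE = {
    "area": (61.31, 6.32),
    "perimeter": (29.43, 1.53),
    "length": (11.20, 0.61),
    "width": (5.65, 0.44),
}
MUTANT_SHAPE = {
    "area": (65.28, 6.29),
    "perimeter": (30.95, 1.65),
    "length": (11.76, 0.62),
    "width": (5.73, 0.37),
}

USABLE_RANGE_NM = (975.0, 1646.0)

# Spectral landmarks (nm): one reflectance peak, two absorption valleys.
PEAK_NM = 1122.81
VALLEY1_NM = 1200.19
VALLEY2_NM = 1483.46


@dataclass(frozen=True)
class ShapeStats:
    """Per-class mean/SD of the four pixel shape features."""

    area: tuple[float, float]
    perimeter: tuple[float, float]
    length: tuple[float, float]
    width: tuple[float, float]

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeStats":
        return cls(tuple(d["area"]), tuple(d["perimeter"]), tuple(d["length"]), tuple(d["width"]))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic acquisition.

    ``image_height``/``image_width`` of ``None`` means "size the tray
    automatically" from the seed count and shape statistics.
    ``offset_band_indices`` restricts the mutant class offset to a subset of
    bands (for planted-band recovery studies); ``None`` applies it to the
    whole spectrum, which is the default condition.
    """

    n_seeds_per_class: tuple[int, int] = (3, 3)
    image_height: int | None = None
    image_width: int | None = None
    n_bands: int = 256
    wl_start: float = 874.41
    wl_end: float = 1733.91
    seed_shape_params: tuple[ShapeStats, ShapeStats] = (
        ShapeStats.from_dict(WT_SHAPE),
        ShapeStats.from_dict(MUTANT_SHAPE),
    )
    class_offset: float = 1.02
    scatter_sd: float = 0.02
    noise_sd: float = 0.01
    edge_noise_gain: float = 4.0
    background_reflectance: float = 0.08
    dark_level: float = 120.0
    white_level: float = 4000.0
    bump_amplitudes: tuple[float, float, float] = (0.06, -0.07, -0.10)
    offset_band_indices: np.ndarray | None = None
    placement: str = "grid"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.wl_start < self.wl_end:
            raise InvalidSpecError("wl_start must be < wl_end")
        if self.n_bands < 2:
            raise InvalidSpecError("n_bands must be >= 2")
        for sd in (self.scatter_sd, self.noise_sd):
            if sd < 0:
                raise InvalidSpecError("noise/scatter SDs must be >= 0")
        if self.class_offset <= 0:
            raise InvalidSpecError("class_offset must be > 0")
        if self.placement not in ("grid", "random"):
            raise InvalidSpecError("placement must be 'grid' or 'random'")
        if any(n < 0 for n in self.n_seeds_per_class):
            raise InvalidSpecError("seed counts must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_bands)

    def cell_size(self) -> int:
        """Side of the placement cell that holds any 3-SD seed plus margin."""
        longest = max(
            st.length[0] + 3 * st.length[1] for st in self.seed_shape_params
        )
        return int(math.ceil(longest)) + 4

    def auto_image_size(self) -> tuple[int, int]:
        n = sum(self.n_seeds_per_class)
        cell = self.cell_size()
        side = max(1, int(math.ceil(math.sqrt(max(n, 1)))))
        extent = side * cell + 2
        return extent, extent

    def resolved_size(self) -> tuple[int, int]:
        h, w = self.image_height, self.image_width
        if h is None or w is None:
            ah, aw = self.auto_image_size()
            h = ah if h is None else h
            w = aw if w is None else w
        return h, w


@dataclass(frozen=True)
class BaseSpectrum:
    """Deterministic seed reflectance curve on the scene's wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray


@dataclass
class SceneTruth:
    """Ground truth for one generated scene."""

    label_raster: np.ndarray  # int32 seed ids, 0 = background
    table: pd.DataFrame  # seed_id, class, area, perimeter, length, width, centroid
    scatter: np.ndarray  # per-seed multiplicative scatter, index = seed_id - 1


def make_base_spectrum(spec: SceneSpec) -> BaseSpectrum:
    """Smooth baseline plus Gaussian features at the landmark wavelengths.

    Deterministic (independent of ``rng_seed``); values stay inside (0, 1).
    """
    wl = spec.wavelengths
    if wl.size < 2:
        raise InvalidSpecError("wavelength grid must have at least 2 points")
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    curve = 0.52 - 0.08 * u  # gentle downward baseline
    a_peak, a_v1, a_v2 = spec.bump_amplitudes
    curve = curve + a_peak * np.exp(-0.5 * ((wl - PEAK_NM) / 30.0) ** 2)
    curve = curve + a_v1 * np.exp(-0.5 * ((wl - VALLEY1_NM) / 25.0) ** 2)
    curve = curve + a_v2 * np.exp(-0.5 * ((wl - VALLEY2_NM) / 45.0) ** 2)
    curve = np.clip(curve, 1e-3, 1 - 1e-3)
    return BaseSpectrum(wavelengths=wl, reflectance=curve)


def offset_for_bayes_accuracy(accuracy: float, scatter_sd: float) -> float:
    """Class offset giving a target Bayes accuracy under the scatter model.

    Per-seed mean reflectance is log-normal with log-SD ``scatter_sd`` in both
    classes and log-mean separation ``ln(offset)``; the optimal single-seed
    classifier then has accuracy ``Phi(ln(offset) / (2 * scatter_sd))``, so

        offset = exp(2 * Phi^{-1}(accuracy) * scatter_sd).
    """
    if not 0.5 < accuracy < 1.0:
        raise ValueError("accuracy must be in (0.5, 1)")
    if scatter_sd <= 0:
        raise ValueError("scatter_sd must be > 0 for a finite offset")
    return float(np.exp(2.0 * ndtri(accuracy) * scatter_sd))


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated normal at +-3 SD with a 1-pixel floor."""
    if sd == 0:
        out = np.full(size, mean)
    else:
        out = truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, size=size, random_state=rng)
    return np.maximum(out, 1.0)


def _ellipse_mask(length: float, width: float, theta: float) -> np.ndarray:
    """Binary mask of a filled rotated ellipse, tight bounding box."""
    a, b = length / 2.0, width / 2.0
    c, s = math.cos(theta), math.sin(theta)
    # bounding half-extents of the rotated ellipse
    hr = math.sqrt((a * s) ** 2 + (b * c) ** 2)
    hc = math.sqrt((a * c) ** 2 + (b * s) ** 2)
    nr, nc = int(math.ceil(2 * hr)) + 1, int(math.ceil(2 * hc)) + 1
    rr, cc = np.mgrid[0:nr, 0:nc]
    dr, dc = rr - (nr - 1) / 2.0, cc - (nc - 1) / 2.0
    # rotate pixel offsets into the ellipse frame (theta = major-axis angle
    # measured from the column axis)
    x = dc * c + dr * s
    y = -dc * s + dr * c
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _class_multiplier(spec: SceneSpec, n_bands: int) -> tuple[np.ndarray, np.ndarray]:
    """(wt, mutant) per-band reflectance multipliers."""
    wt = np.ones(n_bands)
    mut = np.full(n_bands, spec.class_offset)
    if spec.offset_band_indices is not None:
        mut = np.ones(n_bands)
        mut[np.asarray(spec.offset_band_indices, dtype=int)] = spec.class_offset
    return wt, mut


def _place_seeds(spec: SceneSpec, rng: np.random.Generator):
    """Sample shapes and non-overlapping positions for every seed.

    Returns a list of ``(class_label, mask, row0, col0, length, width, theta)``
    in seed-id order, with classes shuffled across positions.
    """
    h, w = spec.resolved_size()
    classes = np.repeat([1, 2], spec.n_seeds_per_class)
    n = classes.size
    lengths = np.empty(n)
    widths = np.empty(n)
    for label, stats in zip((1, 2), spec.seed_shape_params):
        idx = np.flatnonzero(classes == label)
        lengths[idx] = _sample_truncnorm(rng, *stats.length, idx.size)
        widths[idx] = _sample_truncnorm(rng, *stats.width, idx.size)
    widths = np.minimum(widths, lengths)  # major axis stays major
    thetas = rng.uniform(0.0, math.pi, size=n)

    placements = []
    if spec.placement == "grid":
        cell = spec.cell_size()
        rows_fit, cols_fit = (h - 2) // cell, (w - 2) // cell
        if rows_fit * cols_fit < n:
            raise PlacementError(
                f"image {h}x{w} offers {rows_fit * cols_fit} cells of {cell} px "
                f"for {n} seeds"
            )
        cells = [(r, c) for r in range(rows_fit) for c in range(cols_fit)]
        order = rng.permutation(len(cells))[:n]
        for i in range(n):
            mask = _ellipse_mask(lengths[i], widths[i], thetas[i])
            mr, mc = mask.shape
            cr, cc = cells[order[i]]
            # keep >= 1 empty px at the cell's far edge so neighbours never 8-touch
            slack_r, slack_c = cell - mr - 1, cell - mc - 1
            r0 = 1 + cr * cell + int(rng.integers(0, max(slack_r, 0) + 1))
            c0 = 1 + cc * cell + int(rng.integers(0, max(slack_c, 0) + 1))
            placements.append((int(classes[i]), mask, r0, c0, lengths[i], widths[i], thetas[i]))
    else:
        occupancy = np.zeros((h, w), dtype=bool)
        max_tries = 200 * max(n, 1)
        tries = 0
        for i in range(n):
            mask = _ellipse_mask(lengths[i], widths[i], thetas[i])
            mr, mc = mask.shape
            if mr + 2 > h or mc + 2 > w:
                raise PlacementError(f"seed of {mr}x{mc} px cannot fit in {h}x{w} image")
            # grow by one pixel so neighbouring seeds never 8-touch
            grown = binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
            while True:
                tries += 1
                if tries > max_tries:
                    raise PlacementError(
                        f"failed to place seed {i + 1}/{n} after {max_tries} tries"
                    )
                r0 = int(rng.integers(1, h - mr - 1))
                c0 = int(rng.integers(1, w - mc - 1))
                window = occupancy[r0 - 1 : r0 - 1 + mr + 2, c0 - 1 : c0 - 1 + mc + 2]
                if not (window & grown).any():
                    break
            occupancy[r0 : r0 + mr, c0 : c0 + mc] |= mask
            placements.append((int(classes[i]), mask, r0, c0, lengths[i], widths[i], thetas[i]))
    return placements, (h, w)


def generate_scene(
    spec: SceneSpec,
) -> tuple[Hypercube, Hypercube, Hypercube, SceneTruth]:
    """Generate a raw scene cube, dark/white reference frames and ground truth.

    Raw digital numbers follow the push-broom acquisition model

        I_raw = dark + (white - dark) * (R + noise),

    with per-seed reflectance ``R = base * class_multiplier * scatter`` and
    background reflectance elsewhere.  Reference frames are single lines of
    shape ``(cols, bands)`` (1-row cubes) as a line-scan camera records them.
    """
    rng = np.random.default_rng(spec.rng_seed)
    wl = spec.wavelengths
    base = make_base_spectrum(spec).reflectance
    wt_mult, mut_mult = _class_multiplier(spec, spec.n_bands)

    placements, (h, w) = _place_seeds(spec, rng)
    n = len(placements)
    scatter = np.exp(rng.normal(0.0, spec.scatter_sd, size=n)) if spec.scatter_sd > 0 else np.ones(n)

    # reflectance scene
    scene = np.empty((h, w, spec.n_bands), dtype=np.float64)
    scene[:] = spec.background_reflectance
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for i, (label, mask, r0, c0, length, width, theta) in enumerate(placements):
        mult = wt_mult if label == 1 else mut_mult
        spectrum = base * mult * scatter[i]
        region = scene[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        region[mask] = spectrum
        labels[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]][mask] = i + 1
        rr, cc = np.nonzero(mask)
        rows.append(
            {
                "seed_id": i + 1,
                "class": label,
                "area": int(mask.sum()),
                "perimeter": _mask_perimeter(mask),
                "length": length,
                "width": width,
                "theta": theta,
                "centroid_row": r0 + rr.mean(),
                "centroid_col": c0 + cc.mean(),
            }
        )

    # additive sensor noise, inflated outside the usable spectral window
    if spec.noise_sd > 0:
        gain = np.where(
            (wl >= USABLE_RANGE_NM[0]) & (wl <= USABLE_RANGE_NM[1]),
            1.0,
            spec.edge_noise_gain,
        )
        noise = rng.standard_normal(scene.shape)
        noise *= spec.noise_sd * gain
        scene += noise

    # references are frame-averaged in practice, so they carry no noise here
    span = spec.white_level - spec.dark_level
    dark_frame = np.full((w, spec.n_bands), spec.dark_level)
    white_frame = np.full((w, spec.n_bands), spec.white_level)
    raw = scene
    raw *= span
    raw += spec.dark_level

    truth = SceneTruth(
        label_raster=labels,
        table=pd.DataFrame(rows),
        scatter=scatter,
    )
    return (
        Hypercube(raw, wl, kind="raw"),
        reference_frame(dark_frame, wl),
        reference_frame(white_frame, wl),
        truth,
    )


def _mask_perimeter(mask: np.ndarray) -> int:
    """Object pixels 4-adjacent to background or the image border."""
    interior = binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), border_value=0
    )
    return int(mask.sum() - interior.sum())


def generate_spectral_dataset(spec: SceneSpec, n_per_class: int):
    """Emit a labelled spectral matrix directly, bypassing the imaging chain.

    Rows are ``base * class_multiplier * scatter + noise``; class-1 rows come
    first.  Reproducible under a fixed ``rng_seed``.
    """
    from .spectra import SpectralDataset

    if n_per_class < 1:
        raise InvalidSpecError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    wl = spec.wavelengths
    base = make_base_spectrum(spec).reflectance
    wt_mult, mut_mult = _class_multiplier(spec, spec.n_bands)
    n = 2 * n_per_class
    scatter = np.exp(rng.normal(0.0, spec.scatter_sd, size=n)) if spec.scatter_sd > 0 else np.ones(n)
    X = np.empty((n, spec.n_bands))
    X[:n_per_class] = base * wt_mult
    X[n_per_class:] = base * mut_mult
    X *= scatter[:, None]
    if spec.noise_sd > 0:
        gain = np.where(
            (wl >= USABLE_RANGE_NM[0]) & (wl <= USABLE_RANGE_NM[1]),
            1.0,
            spec.edge_noise_gain,
        )
        X += rng.standard_normal(X.shape) * (spec.noise_sd * gain)
    y = np.repeat([1, 2], n_per_class)
    return SpectralDataset(
        X=X,
        wavelengths=wl,
        y=y,
        meta={"source": "generate_spectral_dataset", "rng_seed": spec.rng_seed},
    )


def truth_to_csv(truth: SceneTruth, path) -> None:
    """Write the per-seed ground-truth table as CSV."""
    truth.table.to_csv(path, index=False)
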