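"""Object-wise classification maps of segmented seed scenes.

Each segmented seed's mean spectrum is preprocessed exactly as the training
data were (optional spectral crop and wavelet denoising), restricted to the
model's bands, classified once, and all of the seed's pixels are painted with
that class's colour.  Background pixels keep label 0.  The per-class map
accuracy is the fraction of seeds of each true class labelled correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .cube import Hypercube, crop_spectral_range
from .exceptions import ColourTableError, SeedNIRError
from .morphology import SeedObject
from .spectra import mean_spectrum, wavelet_denoise

__all__ = ["PredictionMap", "DEFAULT_COLOUR_TABLE", "predict_map", "map_accuracy", "render_map"]

# olive / orange for class 1 / 2 of the first variety; pink / navy for a second
DEFAULT_COLOUR_TABLE = {1: (128, 128, 0), 2: (255, 165, 0)}
ALT_COLOUR_TABLE = {1: (255, 105, 180), 2: (0, 0, 128)}
BACKGROUND_RGB = (0, 0, 0)


@dataclass
class PredictionMap:
    """Label raster (0 = background), colour table and per-seed predictions."""

    label_raster: np.ndarray
    colour_table: dict[int, tuple[int, int, int]]
    per_seed: pd.DataFrame  # object_id, predicted, true (nullable)

    def __post_init__(self) -> None:
        predicted = set(int(v) for v in self.per_seed["predicted"])
        missing = predicted - set(self.colour_table)
        if missing:
            raise ColourTableError(
                f"colour table lacks entries for predicted classes {sorted(missing)}"
            )


def predict_map(
    cube: Hypercube,
    seeds: list[SeedObject],
    model,
    bands=None,
    *,
    denoise: bool = True,
    crop: tuple[float, float] | None = None,
    colour_table: dict | None = None,
    truth: dict | None = None,
    mode: str = "object",
) -> PredictionMap:
    """Classify every seed object-wise and paint its pixels.

    ``bands`` is a :class:`~seednir.bands.BandSelection` or index array into
    the (possibly cropped) cube's bands; ``None`` uses all bands.  ``truth``
    optionally maps object_id to the true class.  ``mode="pixel"`` classifies
    each pixel's spectrum individually (diagnostic mode, no denoising).
    """
    if mode not in ("object", "pixel"):
        raise ValueError("mode must be 'object' or 'pixel'")
    if crop is not None:
        cube = crop_spectral_range(cube, *crop)
    if bands is None:
        idx = np.arange(cube.n_bands)
    elif hasattr(bands, "sorted_indices"):
        idx = bands.sorted_indices()
    else:
        idx = np.sort(np.asarray(bands, dtype=int))
    colour_table = dict(colour_table or DEFAULT_COLOUR_TABLE)
    raster = np.zeros(cube.shape[:2], dtype=np.int32)
    rows = []
    for seed in seeds:
        if not seed.mask.any():
            warnings.warn(f"seed {seed.object_id} has an empty mask; skipped", RuntimeWarning)
            continue
        if mode == "object":
            spectrum = mean_spectrum(cube, seed)
            if denoise:
                spectrum = wavelet_denoise(spectrum)
            label = int(model.predict(spectrum[idx][np.newaxis, :])[0])
        else:
            r0, c0 = seed.offset
            px = cube.data[r0 : r0 + seed.mask.shape[0], c0 : c0 + seed.mask.shape[1]][seed.mask]
            votes = model.predict(np.asarray(px, dtype=float)[:, idx])
            vals, counts = np.unique(votes, return_counts=True)
            label = int(vals[np.argmax(counts)])
        rr, cc = seed.full_indices()
        raster[rr, cc] = label
        rows.append(
            {
                "object_id": seed.object_id,
                "predicted": label,
                "true": None if truth is None else truth.get(seed.object_id),
            }
        )
    per_seed = pd.DataFrame(rows, columns=["object_id", "predicted", "true"])
    return PredictionMap(label_raster=raster, colour_table=colour_table, per_seed=per_seed)


def map_accuracy(pmap: PredictionMap, truth: dict) -> dict[int, float]:
    """Per-class accuracy (percent) of the map against a truth table.

    ``truth`` maps object_id -> true class and must cover every seed in the
    map; an unknown object_id raises ``KeyError``.
    """
    per_class_total: dict[int, int] = {}
    per_class_correct: dict[int, int] = {}
    for _, row in pmap.per_seed.iterrows():
        oid = int(row["object_id"])
        if oid not in truth:
            raise KeyError(f"object_id {oid} missing from truth table")
        t = int(truth[oid])
        per_class_total[t] = per_class_total.get(t, 0) + 1
        if int(row["predicted"]) == t:
            per_class_correct[t] = per_class_correct.get(t, 0) + 1
    return {
        c: round(100.0 * per_class_correct.get(c, 0) / n, 2)
        for c, n in sorted(per_class_total.items())
    }


def render_map(pmap: PredictionMap, path=None) -> np.ndarray:
    """Render the label raster to an RGB array; optionally save a PNG.

    Pure function of its inputs: identical maps give byte-identical PNGs.
    """
    h, w = pmap.label_raster.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[:] = BACKGROUND_RGB
    for label, colour in pmap.colour_table.items():
        rgb[pmap.label_raster == label] = colour
    if path is not None:
        Image.fromarray(rgb).save(path, format="PNG")
    return rgb


def save_label_raster(pmap: PredictionMap, path) -> None:
    """Save the label raster as a 16-bit greyscale PNG."""
    Image.fromarray(pmap.label_raster.astype(np.uint16)).save(path, format="PNG")
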