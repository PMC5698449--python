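"""Seed segmentation and pixel-based morphometry.

Seeds are segmented from a single near-infrared band (default: the band
nearest 1139.26 nm, where husk/background contrast is strong) by Otsu
thresholding and 8-connected component labelling.  Four shape features are
measured per seed:

* area: total pixel count of the mask (contour pixels included);
* perimeter: number of object pixels 4-adjacent to background or the border;
* length/width: full major/minor axis lengths of the equivalent ellipse from
  second central moments (pixels treated as unit squares, i.e. a ``1/12``
  variance term per pixel, so a one-pixel-wide object still has finite width).

Thousand-grain weight (TGW) is estimated as ten times the mean mass of
independent 100-seed samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .cube import Hypercube, nearest_band
from .exceptions import SeedNIRError

__all__ = [
    "SeedObject",
    "TGWSummary",
    "select_segmentation_band",
    "segment_seeds",
    "compute_morphology",
    "tgw_from_samples",
    "percent_increase",
]

SEGMENTATION_BAND_NM = 1139.26

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SeedObject:
    """One segmented seed: mask within its bounding box plus shape features."""

    object_id: int
    mask: np.ndarray
    offset: tuple[int, int]  # (row0, col0) of the bounding box
    area_px: int
    perimeter_px: int
    length_px: float
    width_px: float
    centroid: tuple[float, float]
    touches_border: bool = False

    def full_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the mask in full-image coordinates."""
        rr, cc = np.nonzero(self.mask)
        return rr + self.offset[0], cc + self.offset[1]


@dataclass(frozen=True)
class TGWSummary:
    """Mean 100-seed sample mass and the derived thousand-grain weight."""

    mean_sample_mass_g: float
    tgw_g: float


def select_segmentation_band(cube: Hypercube, target_nm: float = SEGMENTATION_BAND_NM) -> np.ndarray:
    """Greyscale image of the band nearest ``target_nm`` (ties to the lower band)."""
    return cube.band(nearest_band(cube.wavelengths, target_nm))


def segment_seeds(
    grey: np.ndarray,
    *,
    min_area: int = 10,
    connectivity: int = 2,
) -> list[SeedObject]:
    """Segment bright seeds from a dark background.

    Otsu's global threshold, 8-connected components (``connectivity=2``),
    components below ``min_area`` discarded.  A constant image yields an
    empty list.  Border-touching objects are kept but flagged.
    """
    grey = np.asarray(grey)
    if not np.all(np.isfinite(grey)):
        raise SeedNIRError("segmentation requires a finite image")
    if np.ptp(grey) == 0:
        return []
    thr = threshold_otsu(grey)
    fg = grey > thr
    labels, n = sk_label(fg, return_num=True, connectivity=connectivity)
    objects: list[SeedObject] = []
    slices = ndimage.find_objects(labels)
    next_id = 1
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        area = int(mask.sum())
        if area < min_area:
            continue
        r0, c0 = sl[0].start, sl[1].start
        touches = (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == grey.shape[0]
            or sl[1].stop == grey.shape[1]
        )
        m = compute_morphology(mask)
        rr, cc = np.nonzero(mask)
        objects.append(
            SeedObject(
                object_id=next_id,
                mask=mask,
                offset=(r0, c0),
                area_px=m.area_px,
                perimeter_px=m.perimeter_px,
                length_px=m.length_px,
                width_px=m.width_px,
                centroid=(r0 + rr.mean(), c0 + cc.mean()),
                touches_border=touches,
            )
        )
        next_id += 1
    return objects


@dataclass(frozen=True)
class Morphometry:
    area_px: int
    perimeter_px: int
    length_px: float
    width_px: float
    orientation_rad: float  # major-axis angle from the column (x) axis


def compute_morphology(mask: np.ndarray) -> Morphometry:
    """Area, 4-adjacency contour perimeter and equivalent-ellipse axes of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise SeedNIRError("morphometry needs a nonempty 2-D mask")
    area = int(mask.sum())
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    perimeter = int(area - int(interior.sum()))
    rr, cc = np.nonzero(mask)
    dr, dc = rr - rr.mean(), cc - cc.mean()
    # unit-square pixel model: each pixel contributes 1/12 to both variances
    mrr = dr @ dr / area + 1.0 / 12.0
    mcc = dc @ dc / area + 1.0 / 12.0
    mrc = dr @ dc / area
    common = np.sqrt(((mrr - mcc) / 2.0) ** 2 + mrc**2)
    lam1 = (mrr + mcc) / 2.0 + common
    lam2 = (mrr + mcc) / 2.0 - common
    length = 4.0 * np.sqrt(max(lam1, 0.0))
    width = 4.0 * np.sqrt(max(lam2, 0.0))
    # angle of the major axis relative to the column axis
    orientation = 0.5 * np.arctan2(2.0 * mrc, mcc - mrr)
    return Morphometry(area, perimeter, float(length), float(width), float(orientation))


def tgw_from_samples(masses_g) -> TGWSummary:
    """Thousand-grain weight from 100-seed sample masses: ``10 x mean``."""
    masses = np.asarray(masses_g, dtype=float)
    if masses.size < 1:
        raise SeedNIRError("need at least one 100-seed sample mass")
    if np.any(masses <= 0) or not np.all(np.isfinite(masses)):
        raise SeedNIRError("sample masses must be positive and finite")
    mean = float(masses.mean())
    return TGWSummary(mean_sample_mass_g=mean, tgw_g=10.0 * mean)


def percent_increase(mutant_mean: float, wt_mean: float) -> float:
    """Percent increase of the mutant mean over wild type, one-decimal rounding."""
    if wt_mean <= 0:
        raise SeedNIRError("wild-type mean must be > 0")
    return round(100.0 * (mutant_mean - wt_mean) / wt_mean, 1)
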