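"""Per-seed mean spectra, wavelet denoising and dataset assembly.

Each segmented seed contributes one sample spectrum: the arithmetic mean of
the calibrated reflectance over its region of interest.  Spectra are denoised
by a level-3 Daubechies-8 discrete wavelet transform with soft universal
thresholding of the detail coefficients (sigma from the median absolute
deviation of the finest details), then collected into a labelled
samples-by-bands matrix (class 1 = wild type, class 2 = mutant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .cube import Hypercube, crop_spectral_range
from .exceptions import SeedNIRError, ShapeMismatchError
from .morphology import SeedObject

__all__ = ["SpectralDataset", "mean_spectrum", "wavelet_denoise", "build_dataset"]


@dataclass
class SpectralDataset:
    """Labelled spectral matrix: ``X`` (samples x bands), wavelengths, labels.

    Labels follow the study's coding: 1 = wild type, 2 = mutant.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ShapeMismatchError("X must be 2-D (samples x bands)")
        if self.y.shape != (self.X.shape[0],):
            raise ShapeMismatchError(
                f"{self.X.shape[0]} rows but {self.y.size} labels"
            )
        if self.wavelengths.shape != (self.X.shape[1],):
            raise ShapeMismatchError(
                f"{self.X.shape[1]} bands but {self.wavelengths.size} wavelengths"
            )
        bad = set(np.unique(self.y)) - {1, 2}
        if bad:
            raise ValueError(f"labels must be 1 (WT) or 2 (mutant); got extra {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, indices) -> "SpectralDataset":
        """Row subset (e.g. a calibration or prediction split)."""
        idx = np.asarray(indices, dtype=int)
        meta = dict(self.meta)
        ids = meta.get("object_ids")
        if ids is not None:
            meta["object_ids"] = list(np.asarray(ids)[idx])
        return SpectralDataset(self.X[idx], self.wavelengths, self.y[idx], meta)

    def select_bands(self, band_indices) -> "SpectralDataset":
        """Column subset restricted to selected bands (kept in wavelength order)."""
        idx = np.sort(np.unique(np.asarray(band_indices, dtype=int)))
        return SpectralDataset(self.X[:, idx], self.wavelengths[idx], self.y, dict(self.meta))

    def crop(self, lo_nm: float, hi_nm: float) -> "SpectralDataset":
        keep = (self.wavelengths >= lo_nm) & (self.wavelengths <= hi_nm)
        if not keep.any():
            raise SeedNIRError(f"no bands in [{lo_nm}, {hi_nm}] nm")
        meta = dict(self.meta)
        meta["crop_nm"] = [float(lo_nm), float(hi_nm)]
        return SpectralDataset(self.X[:, keep], self.wavelengths[keep], self.y, meta)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "label", self.y)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV (one row per seed) plus a JSON sidecar with labels/metadata."""
        path = Path(path)
        pd.DataFrame(self.X, columns=[f"{w:.6f}" for w in self.wavelengths]).to_csv(
            path, index=False
        )
        sidecar = {
            "labels": self.y.tolist(),
            "wavelengths_nm": self.wavelengths.tolist(),
            "meta": {k: _jsonable(v) for k, v in self.meta.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralDataset":
        path = Path(path)
        X = pd.read_csv(path).to_numpy(dtype=float)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            X=X,
            wavelengths=np.asarray(sidecar["wavelengths_nm"], dtype=float),
            y=np.asarray(sidecar["labels"], dtype=int),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def mean_spectrum(cube: Hypercube, seed: SeedObject) -> np.ndarray:
    """Per-band arithmetic mean reflectance over one seed's mask."""
    if not seed.mask.any():
        raise SeedNIRError(f"seed {seed.object_id} has an empty mask")
    r0, c0 = seed.offset
    mr, mc = seed.mask.shape
    if r0 < 0 or c0 < 0 or r0 + mr > cube.shape[0] or c0 + mc > cube.shape[1]:
        raise SeedNIRError(f"seed {seed.object_id} mask falls outside the cube")
    region = cube.data[r0 : r0 + mr, c0 : c0 + mc, :]
    return region[seed.mask].mean(axis=0)


def min_denoise_length(wavelet: str = "db8", level: int = 3) -> int:
    """Shortest spectrum on which a ``level``-deep DWT is well defined."""
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2**level


def wavelet_denoise(
    spectrum: np.ndarray,
    *,
    wavelet: str = "db8",
    level: int = 3,
    threshold: str = "universal_soft",
    mode: str = "symmetric",
) -> np.ndarray:
    """Daubechies-8 level-3 wavelet shrinkage of one spectrum.

    Soft universal threshold ``sigma * sqrt(2 ln n)`` on all detail
    coefficients, with ``sigma`` estimated from the finest-level details as
    ``MAD / 0.6745``.  ``threshold="none"`` reconstructs without shrinkage.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1:
        raise SeedNIRError("wavelet_denoise expects a 1-D spectrum")
    n = s.size
    min_n = min_denoise_length(wavelet, level)
    if pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len) < level:
        raise SeedNIRError(
            f"spectrum of length {n} too short for {wavelet} level {level}; "
            f"need at least {min_n} points"
        )
    coeffs = pywt.wavedec(s, wavelet, level=level, mode=mode)
    if threshold == "universal_soft":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    elif threshold != "none":
        raise ValueError("threshold must be 'universal_soft' or 'none'")
    out = pywt.waverec(coeffs, wavelet, mode=mode)
    return out[:n]


def build_dataset(
    cube: Hypercube,
    seeds: list[SeedObject],
    labels,
    *,
    denoise: bool = True,
    crop: tuple[float, float] | None = None,
    variety: str | None = None,
) -> SpectralDataset:
    """Assemble the labelled spectral matrix from segmented seeds.

    Rows follow ``object_id`` order; optional spectral crop and per-row
    wavelet denoising mirror the preprocessing chain.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(seeds):
        raise ShapeMismatchError(f"{len(seeds)} seeds but {labels.size} labels")
    if crop is not None:
        cube = crop_spectral_range(cube, *crop)
    order = np.argsort([s.object_id for s in seeds])
    X = np.empty((len(seeds), cube.n_bands))
    for row, i in enumerate(order):
        spec = mean_spectrum(cube, seeds[i])
        X[row] = wavelet_denoise(spec) if denoise else spec
    meta = {
        "object_ids": [seeds[i].object_id for i in order],
        "denoised": bool(denoise),
        "crop_nm": list(crop) if crop else None,
    }
    if variety:
        meta["variety"] = variety
    return SpectralDataset(X=X, wavelengths=cube.wavelengths, y=labels[order], meta=meta)
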