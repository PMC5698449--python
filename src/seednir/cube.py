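"""Hyperspectral cube container, reflectance calibration and ENVI-style I/O.

A :class:`Hypercube` is a ``rows x cols x bands`` raster with a strictly
increasing wavelength vector (nm).  Raw sensor cubes are converted to relative
reflectance against dark-current and white-reference frames:

    rho = (I_raw - I_dark) / (I_white - I_dark)

Reference frames may be full cubes or single push-broom frames of shape
``(cols, bands)``, which are broadcast across the scan (row) axis.

On-disk formats: ENVI band-sequential raster with an ASCII ``.hdr`` header
(``samples``, ``lines``, ``bands``, ``wavelength``, ``interleave``,
``data type 4`` = float32), or a single-file NPZ container.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    CalibrationError,
    FormatError,
    ShapeMismatchError,
    SpectralRangeError,
)

__all__ = [
    "Hypercube",
    "reference_frame",
    "calibrate",
    "crop_spectral_range",
    "nearest_band",
    "read_cube",
    "write_cube",
]

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


@dataclass
class Hypercube:
    """Three-dimensional spectral raster plus its wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Raw intensities or relative reflectance.
    wavelengths : ndarray, shape (bands,)
        Band-centre wavelengths in nm, strictly increasing.
    kind : {"raw", "reflectance"}
        Whether the values are sensor counts or calibrated reflectance.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ShapeMismatchError(
                f"cube data must be 3-D (rows, cols, bands); got shape {self.data.shape}"
            )
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ShapeMismatchError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"{self.data.shape[2]} bands"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ShapeMismatchError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, index: int) -> np.ndarray:
        """Return one spatial band image (rows x cols)."""
        return self.data[:, :, index]


def reference_frame(frame: np.ndarray, wavelengths: np.ndarray, kind: str = "raw") -> Hypercube:
    """Wrap a single push-broom reference frame ``(cols, bands)`` as a 1-row cube."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ShapeMismatchError(f"reference frame must be 2-D (cols, bands); got {frame.shape}")
    return Hypercube(frame[np.newaxis, :, :], wavelengths, kind=kind)


def _check_grids(*cubes: Hypercube) -> None:
    ref = cubes[0]
    for c in cubes[1:]:
        if c.n_bands != ref.n_bands or not np.allclose(c.wavelengths, ref.wavelengths):
            raise ShapeMismatchError("cubes do not share a wavelength grid")
        if c.data.shape[1] != ref.data.shape[1]:
            raise ShapeMismatchError(
                f"cube widths differ: {c.data.shape[1]} vs {ref.data.shape[1]}"
            )
        if c.data.shape[0] not in (1, ref.data.shape[0]):
            raise ShapeMismatchError(
                f"reference with {c.data.shape[0]} rows cannot broadcast to "
                f"{ref.data.shape[0]} rows"
            )


def calibrate(
    raw: Hypercube,
    dark: Hypercube,
    white: Hypercube,
    *,
    epsilon: float | None = None,
    on_bad_pixel: str = "sentinel",
) -> Hypercube:
    """Dark/white reflectance correction: ``(raw - dark) / (white - dark)``.

    ``dark`` and ``white`` may be full cubes or single-frame (1-row) cubes,
    broadcast along the scan axis.  Denominator entries with magnitude below
    ``epsilon`` (default ``1e-6`` times the median white level) are either set
    to NaN with a warning (``on_bad_pixel="sentinel"``) or raise
    :class:`CalibrationError` (``on_bad_pixel="error"``).
    """
    if on_bad_pixel not in ("sentinel", "error"):
        raise ValueError("on_bad_pixel must be 'sentinel' or 'error'")
    _check_grids(raw, dark, white)
    num = raw.data.astype(np.float64) - dark.data.astype(np.float64)
    den = white.data.astype(np.float64) - dark.data.astype(np.float64)
    if epsilon is None:
        epsilon = 1e-6 * float(np.median(np.abs(white.data)))
    bad = np.abs(den) <= epsilon
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        if on_bad_pixel == "error":
            raise CalibrationError(
                f"{n_bad} pixel/band entries have |white - dark| <= {epsilon:g}"
            )
        warnings.warn(
            f"calibrate: {n_bad} entries with |white - dark| <= {epsilon:g} set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        den = np.where(bad, np.nan, den)
    return Hypercube(num / den, raw.wavelengths, kind="reflectance")


def crop_spectral_range(cube: Hypercube, lo_nm: float, hi_nm: float) -> Hypercube:
    """Keep exactly the bands with ``lo_nm <= wavelength <= hi_nm`` (closed interval)."""
    if not lo_nm < hi_nm:
        raise SpectralRangeError(f"need lo_nm < hi_nm; got ({lo_nm}, {hi_nm})")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise SpectralRangeError(
            f"no bands in [{lo_nm}, {hi_nm}] nm; cube covers "
            f"[{cube.wavelengths[0]:.2f}, {cube.wavelengths[-1]:.2f}] nm"
        )
    return Hypercube(cube.data[:, :, keep], cube.wavelengths[keep], kind=cube.kind)


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties break toward the lower wavelength."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    d = np.abs(wavelengths - target_nm)
    # np.argmin returns the first (lowest-index == lowest-wavelength) minimum.
    return int(np.argmin(d))


# ---------------------------------------------------------------------------
# ENVI + NPZ I/O
# ---------------------------------------------------------------------------

_REQUIRED_HDR = ("samples", "lines", "bands", "data type", "interleave", "wavelength")


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("header does not start with the ENVI magic line")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read a cube from an ENVI header/raster pair or an NPZ container."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return Hypercube(z["data"], z["wavelengths"], kind=str(z["kind"]))
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"header file not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    for key in _REQUIRED_HDR:
        if key not in fields:
            raise FormatError(f"ENVI header missing required field: {key!r}")
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unsupported interleave: {fields['interleave']!r}")
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported data type code: {dtype_code}")
    rows, cols, bands = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError("wavelength field must be a brace-delimited list")
    wavelengths = np.array([float(w) for w in wl_text[1:-1].split(",") if w.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list has {wavelengths.size} entries for {bands} bands"
        )
    raster = hdr.with_suffix(".raw")
    if not raster.exists():
        raise FormatError(f"raster file not found: {raster}")
    flat = np.fromfile(raster, dtype=_ENVI_DTYPES[dtype_code])
    if flat.size != rows * cols * bands:
        raise FormatError(
            f"raster holds {flat.size} values; header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(rows, cols, bands)
    kind = fields.get("seednir kind", "raw")
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind=kind)


def write_cube(cube: Hypercube, path: str | Path) -> Path:
    """Write a cube as ENVI BSQ float32 (``.hdr`` + ``.raw``) or as NPZ.

    Returns the header (or NPZ) path written.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            kind=np.str_(cube.kind),
        )
        return path
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    raster = hdr.with_suffix(".raw")
    data = np.asarray(cube.data, dtype=np.float32)
    rows, cols, bands = data.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"seednir kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    data.transpose(2, 0, 1).tofile(raster)
    return hdr
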