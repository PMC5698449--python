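"""Exception hierarchy for seednir."""


class SeedNIRError(Exception):
    """Base class for all seednir errors."""


class InvalidSpecError(SeedNIRError, ValueError):
    """A scene or model specification violates its invariants."""


class ShapeMismatchError(SeedNIRError, ValueError):
    """Array dimensions or wavelength grids do not agree."""


class SpectralRangeError(SeedNIRError, ValueError):
    """A requested wavelength range selects no bands."""


class FormatError(SeedNIRError, ValueError):
    """A file on disk does not conform to the expected dialect."""


class PlacementError(SeedNIRError, RuntimeError):
    """Seeds could not be placed in the scene without overlap."""


class DegenerateDataError(SeedNIRError, ValueError):
    """Input data carry no variance (or otherwise defeat the estimator)."""


class CalibrationError(SeedNIRError, ValueError):
    """Dark/white referencing failed (near-zero denominator in error mode)."""


class ColourTableError(SeedNIRError, KeyError):
    """A predicted class has no entry in the colour table."""
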