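"""Informative-wavelength selection.

Two selectors are provided:

* **SPA** (successive projections algorithm): a forward selector that, from a
  given start band, repeatedly appends the band whose spectral column has the
  largest norm after projection onto the orthogonal complement of the bands
  already chosen — minimising collinearity.  The final subset (start band and
  chain length) is the one minimising the root-mean-square error of
  validation (RMSEV) of a multiple linear regression of the numeric class
  labels on the chosen bands.
* **PCA-loading peaks**: local maxima and minima of the first few PCA loading
  curves, which mark the wavelengths that dominate the spectral variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import SeedNIRError
from .pca import PCAModel

__all__ = ["BandSelection", "spa_chain", "spa_select", "loading_peaks"]

logger = logging.getLogger(__name__)


@dataclass
class BandSelection:
    """Selected band indices (in selection order) with their wavelengths."""

    method: str  # "SPA" or "PCA_loadings"
    indices: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    criterion_trace: np.ndarray | None = None  # best RMSEV per subset size (SPA)
    start_index: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(set(self.indices.tolist())) != self.indices.size:
            raise SeedNIRError("selected band indices must be unique")

    @property
    def n_selected(self) -> int:
        return self.indices.size

    def sorted_indices(self) -> np.ndarray:
        return np.sort(self.indices)


def spa_chain(X: np.ndarray, start_index: int, chain_length: int) -> np.ndarray:
    """Successive-projections chain of column indices from ``start_index``.

    At each step the column with maximal residual norm after projecting out
    the span of the already-chosen columns is appended; ties break to the
    lowest index.  If the residual space degenerates first, the truncated
    chain is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_index < p:
        raise SeedNIRError(f"start_index must be in [0, {p - 1}]")
    if not 1 <= chain_length <= min(n, p):
        raise SeedNIRError(f"chain_length must be in [1, {min(n, p)}]")
    R = X.copy()  # residuals of every column against the selected span
    scale = max(float(np.linalg.norm(X, axis=0).max()), 1.0)
    chain = [int(start_index)]
    selected = np.zeros(p, dtype=bool)
    selected[start_index] = True
    for _ in range(chain_length - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv <= 1e-12 * scale:
            warnings.warn(
                f"SPA chain truncated at {len(chain)} bands: residual space exhausted",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        q = v / nv
        R -= np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        nxt = int(np.argmax(norms))  # first max = lowest index on ties
        if norms[nxt] <= 1e-12 * scale:
            warnings.warn(
                f"SPA chain truncated at {len(chain)} bands: residual space exhausted",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        chain.append(nxt)
        selected[nxt] = True
    return np.asarray(chain, dtype=int)


def _mlr_rmsev(Xcal, ycal, Xval, yval, cols) -> float:
    """RMSEV of an intercept MLR of y on the given columns."""
    A = np.column_stack([np.ones(Xcal.shape[0]), Xcal[:, cols]])
    beta, _, rank, _ = np.linalg.lstsq(A, ycal, rcond=None)
    if rank < A.shape[1]:
        logger.info("rank-deficient MLR design (%d cols); ridge fallback", len(cols))
        G = A.T @ A + 1e-8 * np.eye(A.shape[1])
        beta = np.linalg.solve(G, A.T @ ycal)
    Av = np.column_stack([np.ones(Xval.shape[0]), Xval[:, cols]])
    resid = yval - Av @ beta
    return float(np.sqrt(np.mean(resid**2)))


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    max_vars: int = 15,
    *,
    wavelengths: np.ndarray | None = None,
    min_vars: int = 1,
) -> BandSelection:
    """Full SPA: chains from every start band, subset chosen by minimum RMSEV.

    For every start column and every chain prefix of size ``m`` in
    ``[min_vars, max_vars]``, an intercept MLR of the numeric labels on the
    prefix is fitted on the calibration set and scored by RMSEV on the
    validation set; the global minimiser wins (ties: fewer bands, then lower
    start index).  ``criterion_trace[m - 1]`` records the best RMSEV at size
    ``m`` over all starts.
    """
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    ycal = np.asarray(ycal, dtype=float)
    yval = np.asarray(yval, dtype=float)
    if Xval.shape[0] < 1:
        raise SeedNIRError("validation set must be nonempty")
    n, p = Xcal.shape
    max_vars = int(min(max_vars, n - 1, p))
    if max_vars < 1:
        raise SeedNIRError("max_vars must be >= 1 after clipping to n_cal - 1")
    best = None  # (rmsev, m, start, chain_prefix)
    trace = np.full(max_vars, np.inf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # truncated chains are fine here
        for start in range(p):
            chain = spa_chain(Xcal, start, max_vars)
            for m in range(min_vars, chain.size + 1):
                rmsev = _mlr_rmsev(Xcal, ycal, Xval, yval, chain[:m])
                if rmsev < trace[m - 1]:
                    trace[m - 1] = rmsev
                key = (rmsev, m, start)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (rmsev, m, start, chain[:m].copy())
    rmsev, m, start, sel = best
    return BandSelection(
        method="SPA",
        indices=sel,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[sel],
        criterion_trace=trace,
        start_index=start,
    )


def loading_peaks(
    model: PCAModel,
    n_components: int = 3,
    prominence: float = 0.05,
    *,
    wavelengths: np.ndarray | None = None,
) -> BandSelection:
    """Peaks and valleys of the first ``n_components`` PCA loading curves.

    ``prominence`` is relative to each curve's range.  Extrema from all
    curves are pooled, sorted by band index, and near-duplicates (adjacent
    bands) merged, keeping the first.
    """
    if n_components > model.n_components:
        raise SeedNIRError(
            f"asked for {n_components} loading curves; model has {model.n_components}"
        )
    hits: list[int] = []
    for c in range(n_components):
        curve = model.loadings[:, c]
        rng = float(np.ptp(curve))
        if rng == 0:
            continue
        prom = prominence * rng
        for sgn in (1.0, -1.0):
            pk, _ = find_peaks(sgn * curve, prominence=prom)
            hits.extend(int(i) for i in pk)
    hits = sorted(set(hits))
    merged: list[int] = []
    for idx in hits:
        if merged and idx - merged[-1] <= 1:
            continue
        merged.append(idx)
    sel = np.asarray(merged, dtype=int)
    return BandSelection(
        method="PCA_loadings",
        indices=sel,
        wavelengths_nm=None if wavelengths is None else np.asarray(wavelengths)[sel],
    )
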