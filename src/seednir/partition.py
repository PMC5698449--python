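"""Kennard-Stone calibration/prediction partitioning.

The Kennard-Stone algorithm deterministically builds a calibration subset
that spans the spectral space: it starts from the two most distant samples
(Euclidean distance) and then repeatedly adds the sample whose minimum
distance to the already-selected set is largest.  The remainder forms the
prediction set.  A 2:1 ratio on 660 samples yields 440 calibration and 220
prediction rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import SeedNIRError

__all__ = ["SplitResult", "n_cal_from_ratio", "kennard_stone_split"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index sets.

    ``cal_indices`` is in Kennard-Stone selection order (so the first ``k``
    entries are exactly the selection at size ``k``); ``pred_indices`` is the
    sorted complement.
    """

    cal_indices: np.ndarray
    pred_indices: np.ndarray
    ratio: float

    @property
    def n_cal(self) -> int:
        return self.cal_indices.size

    @property
    def n_pred(self) -> int:
        return self.pred_indices.size


def n_cal_from_ratio(n: int, cal_parts: int = 2, pred_parts: int = 1) -> int:
    """Calibration size from a parts ratio, half-up rounding (660 at 2:1 -> 440)."""
    frac = cal_parts / (cal_parts + pred_parts)
    return int(math.floor(n * frac + 0.5))


def kennard_stone_split(X: np.ndarray, n_cal: int) -> SplitResult:
    """Select ``n_cal`` calibration samples by the Kennard-Stone max-min rule.

    Deterministic; distance ties break toward the lowest index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SeedNIRError("X must be 2-D (samples x features)")
    n = X.shape[0]
    if not 2 <= n_cal <= n - 1:
        raise SeedNIRError(f"n_cal must be in [2, {n - 1}]; got {n_cal}")
    D = squareform(pdist(X, metric="euclidean"))
    # farthest pair; argmax of the row-major flattened matrix returns the
    # lexicographically smallest (i, j), i.e. the lowest-index tie-break
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(i), int(j)]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[[i, j]] = True
    min_dist = np.minimum(D[i], D[j])
    min_dist[in_cal] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))  # first occurrence = lowest index
        selected.append(nxt)
        in_cal[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[in_cal] = -np.inf
    cal = np.asarray(selected, dtype=int)
    pred = np.flatnonzero(~in_cal)
    return SplitResult(cal_indices=cal, pred_indices=pred, ratio=n_cal / n)
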