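"""Exploratory principal component analysis of seed mean spectra.

Mean-centred PCA (no variance scaling, the convention for reflectance
spectra).  Loadings are orthonormal with a deterministic sign convention
(largest-magnitude element of each loading positive) so loading-curve
peak/valley picking is reproducible; explained percentages are relative to
the total variance, so they sum to 100 over all components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .exceptions import DegenerateDataError, SeedNIRError

__all__ = ["PCAModel", "fit_pca", "explained_sum", "plot_scores_3d", "export_loadings_csv"]


@dataclass
class PCAModel:
    """Fitted PCA: per-band mean, loadings (bands x k), scores, explained %."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_pct: np.ndarray
    scores: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_spectrum) @ self.loadings


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Column-mean-centred PCA with ``k`` components (full SVD)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SeedNIRError("PCA needs a 2-D matrix with at least 2 samples")
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise SeedNIRError(f"k must be in [1, {min(n - 1, p)}]; got {k}")
    if np.allclose(X, X[0], atol=0, rtol=0) or np.allclose(X.var(axis=0), 0):
        raise DegenerateDataError("data carry no variance; PCA is undefined")
    sk = _SKPCA(n_components=k, svd_solver="full")
    scores = sk.fit_transform(X)
    loadings = sk.components_.T.copy()  # bands x k
    # sign convention: each loading's largest-magnitude element is positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = scores * flip
    return PCAModel(
        mean_spectrum=sk.mean_.copy(),
        loadings=loadings,
        explained_pct=100.0 * sk.explained_variance_ratio_.copy(),
        scores=scores,
    )


def explained_sum(model_or_pcts, first_k: int | None = None) -> float:
    """Sum of the first ``first_k`` explained-variance percentages.

    Accepts a :class:`PCAModel` or a plain sequence of percentages, so the
    bookkeeping (e.g. 93.95 + 5.31 + 0.38 = 99.64) can be checked directly.
    """
    pcts = (
        model_or_pcts.explained_pct
        if isinstance(model_or_pcts, PCAModel)
        else np.asarray(model_or_pcts, dtype=float)
    )
    if first_k is None:
        first_k = len(pcts)
    if not 0 <= first_k <= len(pcts):
        raise SeedNIRError(f"first_k must be in [0, {len(pcts)}]")
    return float(np.sum(pcts[:first_k]))


def plot_scores_3d(model: PCAModel, y=None, path=None, class_names=None):
    """3-D score plot of the first three components, coloured by class.

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if model.n_components < 3:
        raise SeedNIRError("score plot needs at least 3 fitted components")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    scores = model.scores
    if y is None:
        ax.scatter(scores[:, 0], scores[:, 1], scores[:, 2], s=12)
    else:
        y = np.asarray(y)
        for cls in np.unique(y):
            m = y == cls
            label = (class_names or {}).get(cls, f"class {cls}")
            ax.scatter(scores[m, 0], scores[m, 1], scores[m, 2], s=12, label=label)
        ax.legend()
    for axis, i in zip(("x", "y", "z"), range(3)):
        getattr(ax, f"set_{axis}label")(f"PC{i + 1} ({model.explained_pct[i]:.2f}%)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def export_loadings_csv(model: PCAModel, wavelengths, path) -> None:
    """Write loading curves and explained percentages as CSV."""
    import pandas as pd

    df = pd.DataFrame(
        model.loadings,
        columns=[
            f"PC{i + 1}_{model.explained_pct[i]:.4f}pct" for i in range(model.n_components)
        ],
    )
    df.insert(0, "wavelength_nm", np.asarray(wavelengths, dtype=float))
    df.to_csv(path, index=False)
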