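"""Top-level modelling interface: ``SeedDiscrimination`` and its results.

This is the one-stop entry point for the chemometric half of the pipeline.
Build the model from a labelled spectral dataset (or a DataFrame), call
:meth:`SeedDiscrimination.fit`, and read accuracies, selected wavelengths and
confusion tables off the returned :class:`DiscriminationResults`:

>>> ds = generate_spectral_dataset(SceneSpec(rng_seed=7), n_per_class=120)
>>> res = SeedDiscrimination.from_dataset(ds).fit(bands="spa", classifier="svm")
>>> print(res.summary())

``fit`` runs: optional spectral crop to the usable window -> per-row wavelet
denoising -> Kennard-Stone 2:1 calibration/prediction split -> band selection
(SPA with an inner Kennard-Stone validation sub-split, PCA-loading peaks, or
the full spectrum) -> classifier training (grid-searched RBF SVM or ELM with
tuned hidden-node count) -> evaluation on both sets.  The prediction set is
never used for any tuning decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandSelection, loading_peaks, spa_select
from .classify import EvalReport, evaluate, train_elm, train_svm
from .exceptions import SeedNIRError
from .mapping import PredictionMap, predict_map
from .partition import SplitResult, kennard_stone_split, n_cal_from_ratio
from .pca import PCAModel, fit_pca
from .spectra import SpectralDataset, wavelet_denoise
from .synthetic import USABLE_RANGE_NM

__all__ = ["SeedDiscrimination", "DiscriminationResults"]


class SeedDiscrimination:
    """Two-class seed discrimination model over NIR mean spectra.

    Parameters
    ----------
    X : ndarray, samples x bands
    y : array of class labels (1 = wild type, 2 = mutant)
    wavelengths : band-centre wavelengths in nm (optional; needed for
        spectral cropping and wavelength reporting)
    variety : free-text identifier carried into reports
    """

    def __init__(self, X, y, wavelengths=None, variety: str | None = None):
        X = np.asarray(X, dtype=float)
        if wavelengths is None:
            wavelengths = np.arange(X.shape[1], dtype=float)
        self.dataset = SpectralDataset(
            X=X, wavelengths=wavelengths, y=y, meta={"variety": variety} if variety else {}
        )
        self.variety = variety

    @classmethod
    def from_dataset(cls, ds: SpectralDataset) -> "SeedDiscrimination":
        m = cls.__new__(cls)
        m.dataset = ds
        m.variety = ds.meta.get("variety")
        return m

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", variety: str | None = None
    ) -> "SeedDiscrimination":
        """Wide DataFrame: one row per seed, wavelength-named spectral columns."""
        if label_col not in df.columns:
            raise SeedNIRError(f"label column {label_col!r} not in DataFrame")
        y = df[label_col].to_numpy(dtype=int)
        spec_cols = [c for c in df.columns if c != label_col]
        try:
            wl = np.asarray([float(c) for c in spec_cols])
        except ValueError as err:
            raise SeedNIRError(
                "spectral column names must be numeric wavelengths"
            ) from err
        return cls(df[spec_cols].to_numpy(dtype=float), y, wavelengths=wl, variety=variety)

    def fit(
        self,
        bands: str = "spa",
        classifier: str = "svm",
        *,
        ratio: tuple[int, int] = (2, 1),
        denoise: bool = True,
        crop: tuple[float, float] | None = USABLE_RANGE_NM,
        max_vars: int = 15,
        n_components: int = 3,
        prominence: float = 0.05,
        seed: int = 0,
    ) -> "DiscriminationResults":
        """Run the discrimination pipeline and return a results object.

        ``bands``: ``"spa"``, ``"loadings"`` or ``"full"``.
        ``classifier``: ``"svm"`` or ``"elm"``.  All randomness (CV folds,
        ELM weights) derives from ``seed``.
        """
        if bands not in ("spa", "loadings", "full"):
            raise SeedNIRError("bands must be 'spa', 'loadings' or 'full'")
        if classifier not in ("svm", "elm"):
            raise SeedNIRError("classifier must be 'svm' or 'elm'")
        ds = self.dataset
        if crop is not None:
            ds = ds.crop(*crop)
        if denoise:
            Xd = np.apply_along_axis(wavelet_denoise, 1, ds.X)
            ds = SpectralDataset(Xd, ds.wavelengths, ds.y, dict(ds.meta))

        split = kennard_stone_split(ds.X, n_cal_from_ratio(ds.n_samples, *ratio))
        cal, pred = ds.subset(split.cal_indices), ds.subset(split.pred_indices)

        pca_model = None
        if bands == "full":
            selection = None
            band_idx = np.arange(ds.n_bands)
        elif bands == "spa":
            inner = kennard_stone_split(cal.X, n_cal_from_ratio(cal.n_samples, *ratio))
            selection = spa_select(
                cal.X[inner.cal_indices],
                cal.y[inner.cal_indices],
                cal.X[inner.pred_indices],
                cal.y[inner.pred_indices],
                max_vars=max_vars,
                wavelengths=ds.wavelengths,
            )
            band_idx = selection.sorted_indices()
        else:
            pca_model = fit_pca(cal.X, k=min(n_components, cal.n_samples - 1, ds.n_bands))
            selection = loading_peaks(
                pca_model, n_components=pca_model.n_components,
                prominence=prominence, wavelengths=ds.wavelengths,
            )
            if selection.n_selected == 0:
                raise SeedNIRError("loading-peak selection found no bands")
            band_idx = selection.sorted_indices()

        Xc, Xp = cal.X[:, band_idx], pred.X[:, band_idx]
        if classifier == "svm":
            clf, c, g = train_svm(Xc, cal.y, seed=seed)
            params = {"kind": "SVM", "c": c, "g": g}
        else:
            clf, k = train_elm(Xc, cal.y, rng_seed=seed + 1)
            params = {"kind": "ELM", "n_hidden": k}
        params["bands"] = bands
        params["n_bands_used"] = int(band_idx.size)
        report = evaluate(clf, Xc, cal.y, Xp, pred.y, params=params)
        # preprocessing a fresh cube needs at map time: include any crop or
        # denoising already baked into the input dataset upstream of fit()
        meta = self.dataset.meta
        meta_crop = meta.get("crop_nm")
        map_pre = {
            "denoise": bool(denoise or meta.get("denoised", False)),
            "crop": crop if crop is not None else (tuple(meta_crop) if meta_crop else None),
        }
        return DiscriminationResults(
            model=self,
            classifier=clf,
            dataset=ds,
            split=split,
            band_selection=selection,
            band_indices=band_idx,
            report=report,
            pca=pca_model,
            seed=seed,
            preprocessing=map_pre,
        )


@dataclass
class DiscriminationResults:
    """Fitted pipeline: split, selected bands, classifier, accuracies."""

    model: SeedDiscrimination
    classifier: object
    dataset: SpectralDataset  # preprocessed (cropped/denoised) data the fit used
    split: SplitResult
    band_selection: BandSelection | None
    band_indices: np.ndarray
    report: EvalReport
    pca: PCAModel | None = None
    seed: int = 0
    preprocessing: dict = field(default_factory=dict)

    # -- convenience accessors --------------------------------------------
    @property
    def accuracy_cal(self) -> float:
        return self.report.accuracy_cal

    @property
    def accuracy_pred(self) -> float:
        return self.report.accuracy_pred

    @property
    def params(self) -> dict:
        return self.report.params

    @property
    def selected_wavelengths_nm(self) -> np.ndarray:
        return self.dataset.wavelengths[self.band_indices]

    def predict(self, X) -> np.ndarray:
        """Classify preprocessed spectra given on the fit's band grid."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.dataset.n_bands:
            X = X[:, self.band_indices]
        return self.classifier.predict(X)

    def predict_map(self, cube, seeds, truth: dict | None = None, **kwargs) -> PredictionMap:
        """Object-wise classification map with this fit's preprocessing."""
        pre = self.preprocessing
        return predict_map(
            cube,
            seeds,
            self.classifier,
            bands=self.band_indices,
            denoise=pre.get("denoise", True),
            crop=pre.get("crop"),
            truth=truth,
            **kwargs,
        )

    def summary(self) -> str:
        """Human-readable report in the spirit of a regression summary table."""
        p = self.report.params
        lines = []
        title = "Seed discrimination results"
        if self.model.variety:
            title += f" ({self.model.variety})"
        rule = "=" * 58
        lines += [rule, title.center(58), rule]

        def row(k, v):
            lines.append(f"{k:<32}{v:>26}")

        row("No. samples", self.dataset.n_samples)
        row("Calibration / prediction", f"{self.split.n_cal} / {self.split.n_pred}")
        row("Bands used", f"{p['n_bands_used']} ({p['bands']})")
        row("Classifier", p["kind"])
        if p["kind"] == "SVM":
            row("(c, g)", f"({p['c']:g}, {p['g']:g})")
        else:
            row("Hidden nodes", p["n_hidden"])
        row("Calibration accuracy", f"{self.accuracy_cal:.2f}%")
        row("Prediction accuracy", f"{self.accuracy_pred:.2f}%")
        if self.band_selection is not None and self.band_selection.wavelengths_nm is not None:
            wl = ", ".join(f"{w:.2f}" for w in np.sort(self.band_selection.wavelengths_nm))
            lines += ["-" * 58, "Selected wavelengths (nm):", f"  {wl}"]
        lines += [rule]
        return "\n".join(lines)
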