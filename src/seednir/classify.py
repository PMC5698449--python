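"""Discrimination models: RBF-kernel SVM and extreme learning machine (ELM).

The SVM is scikit-learn's C-SVC with a radial basis kernel; the penalty ``c``
and kernel width ``g`` are tuned on a powers-of-two grid by stratified 5-fold
cross-validation on the calibration set (ties prefer smaller ``c``, then
smaller ``g``).

The ELM is a single-hidden-layer feedforward network whose input weights and
biases are drawn once at random and never updated; only the output weights
are estimated, by least squares against one-hot class targets.  Inputs are
min-max scaled to [0, 1] per band using calibration-set ranges (the logistic
hidden units need bounded inputs).  The hidden-node count is tuned over
1..80 on an inner Kennard-Stone validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import SeedNIRError, ShapeMismatchError
from .partition import kennard_stone_split, n_cal_from_ratio

__all__ = [
    "ELMClassifier",
    "train_svm",
    "train_elm",
    "evaluate",
    "EvalReport",
    "DEFAULT_C_GRID",
    "DEFAULT_G_GRID",
]

DEFAULT_C_GRID = tuple(2.0**k for k in range(-2, 11))
DEFAULT_G_GRID = tuple(2.0**k for k in range(-6, 7))


def _check_two_classes(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise SeedNIRError("training data must contain both classes")
    return y


def train_svm(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    g_grid=DEFAULT_G_GRID,
    *,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[SVC, float, float]:
    """Grid-searched RBF SVM; returns (fitted model, chosen c, chosen g)."""
    Xcal = np.asarray(Xcal, dtype=float)
    ycal = _check_two_classes(ycal)
    folds = list(
        StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(Xcal, ycal)
    )
    best_acc, best_c, best_g = -1.0, None, None
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            correct = 0
            for tr, te in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(Xcal[tr], ycal[tr])
                correct += int(np.sum(clf.predict(Xcal[te]) == ycal[te]))
            acc = correct / Xcal.shape[0]
            if acc > best_acc:  # strict: ties keep the smaller (c, g)
                best_acc, best_c, best_g = acc, c, g
    model = SVC(C=best_c, gamma=best_g, kernel="rbf")
    model.fit(Xcal, ycal)
    return model, best_c, best_g


class ELMClassifier:
    """Sigmoid extreme learning machine for two-class spectra.

    Input weights/biases are uniform on [-1, 1], fixed by ``rng_seed``;
    output weights solve a least-squares problem against one-hot targets.
    """

    def __init__(self, n_hidden: int, rng_seed: int = 0):
        if not 1 <= n_hidden <= 80:
            raise SeedNIRError(f"n_hidden must be in [1, 80]; got {n_hidden}")
        self.n_hidden = int(n_hidden)
        self.rng_seed = int(rng_seed)
        self._fitted = False

    # -- internals ---------------------------------------------------------
    def _hidden(self, X: np.ndarray) -> np.ndarray:
        Z = np.clip((X - self._mins) / self._ranges, 0.0, 1.0)
        A = Z @ self._W.T + self._b
        H = 1.0 / (1.0 + np.exp(-A))
        # constant column = output-layer bias, so even one hidden node can
        # place a decision boundary along its activation
        return np.column_stack([H, np.ones(H.shape[0])])

    # -- scikit-learn-ish surface -----------------------------------------
    def fit(self, X: np.ndarray, y) -> "ELMClassifier":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        self.classes_ = np.unique(y)
        self._mins = X.min(axis=0)
        ranges = X.max(axis=0) - self._mins
        ranges[ranges == 0] = 1.0
        self._ranges = ranges
        rng = np.random.default_rng(self.rng_seed)
        # draw the full 80-node bank so nested node counts share weights
        W_full = rng.uniform(-1.0, 1.0, size=(80, X.shape[1]))
        b_full = rng.uniform(-1.0, 1.0, size=80)
        self._W = W_full[: self.n_hidden]
        self._b = b_full[: self.n_hidden]
        H = self._hidden(X)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self._beta, *_ = np.linalg.lstsq(H, T, rcond=None)
        self._fitted = True
        return self

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise SeedNIRError("ELM is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._W.shape[1]:
            raise ShapeMismatchError(
                f"model expects {self._W.shape[1]} bands; got {X.shape[1]}"
            )
        return self._hidden(X) @ self._beta

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_values(X), axis=1)]


def train_elm(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    n_hidden_range=range(1, 81),
    rng_seed: int = 0,
) -> tuple[ELMClassifier, int]:
    """Tune the hidden-node count on an inner Kennard-Stone 2:1 sub-split.

    Returns the model refitted on the full calibration set at the chosen
    count (ties prefer fewer nodes).
    """
    Xcal = np.asarray(Xcal, dtype=float)
    ycal = _check_two_classes(ycal)
    split = kennard_stone_split(Xcal, n_cal_from_ratio(Xcal.shape[0]))
    tr, va = split.cal_indices, split.pred_indices
    if np.unique(ycal[tr]).size < 2 or va.size == 0:
        tr, va = np.arange(Xcal.shape[0]), np.arange(Xcal.shape[0])
    best_acc, best_k = -1.0, None
    for k in n_hidden_range:
        elm = ELMClassifier(k, rng_seed=rng_seed).fit(Xcal[tr], ycal[tr])
        acc = float(np.mean(elm.predict(Xcal[va]) == ycal[va]))
        if acc > best_acc:
            best_acc, best_k = acc, k
    model = ELMClassifier(best_k, rng_seed=rng_seed).fit(Xcal, ycal)
    return model, best_k


@dataclass
class EvalReport:
    """Calibration/prediction accuracies, confusion tables, chosen parameters."""

    accuracy_cal: float
    accuracy_pred: float
    confusion_cal: pd.DataFrame
    confusion_pred: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy_cal": self.accuracy_cal,
            "accuracy_pred": self.accuracy_pred,
            "confusion_cal": self.confusion_cal.to_dict(),
            "confusion_pred": self.confusion_pred.to_dict(),
            "params": dict(self.params),
        }


def _accuracy_and_confusion(model, X, y) -> tuple[float, pd.DataFrame]:
    y = np.asarray(y, dtype=int)
    yhat = model.predict(np.asarray(X, dtype=float))
    acc = round(100.0 * float(np.mean(yhat == y)), 2)
    labels = sorted(set(y.tolist()) | set(np.asarray(yhat).tolist()))
    cm = confusion_matrix(y, yhat, labels=labels)
    df = pd.DataFrame(
        cm,
        index=pd.Index(labels, name="true"),
        columns=pd.Index(labels, name="predicted"),
    )
    return acc, df


def evaluate(model, Xcal, ycal, Xpred, ypred, params: dict | None = None) -> EvalReport:
    """Accuracy (percent, 2 decimals) and confusion tables on both sets."""
    Xcal = np.asarray(Xcal, dtype=float)
    Xpred = np.asarray(Xpred, dtype=float)
    n_feat = getattr(model, "n_features_in_", None)
    if n_feat is None and hasattr(model, "_W"):
        n_feat = model._W.shape[1]
    if n_feat is not None and (Xcal.shape[1] != n_feat or Xpred.shape[1] != n_feat):
        raise ShapeMismatchError(
            f"model expects {n_feat} bands; got cal={Xcal.shape[1]}, pred={Xpred.shape[1]}"
        )
    acc_cal, cm_cal = _accuracy_and_confusion(model, Xcal, ycal)
    acc_pred, cm_pred = _accuracy_and_confusion(model, Xpred, ypred)
    return EvalReport(
        accuracy_cal=acc_cal,
        accuracy_pred=acc_pred,
        confusion_cal=cm_cal,
        confusion_pred=cm_pred,
        params=dict(params or {}),
    )
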