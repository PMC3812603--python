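"""Soft-margin SVM over the band-power features.

:class:`AttentionSVC` is a scikit-learn-compatible binary classifier:
attentive maps to +1, inattentive to −1, and the decision function is the
usual kernelized soft-margin SVM, with the package's own polynomial
kernels (:mod:`eegattn.kernels`) injected into libsvm's SMO solver as a
Gram-matrix callable. A decision value of exactly zero is resolved to
*attentive*: falsely flagging an attentive student as inattentive is the
costlier mistake in the intended classroom use.

Band energies span orders of magnitude (delta sits near 10⁴ μV² while
beta sits near 10²), so by default features are z-scored on the training
set before entering the kernel; set ``standardize=False`` for the kernel
on raw energies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS
from .io import ATTENTIVE, INATTENTIVE
from .kernels import KernelSpec, gram_matrix

CLASS_MAP = {ATTENTIVE: 1, INATTENTIVE: -1}

_ARCHIVE_VERSION = 1


class AttentionSVC(ClassifierMixin, BaseEstimator):
    """Polynomial-kernel SVM for attentive-vs-inattentive classification.

    Parameters
    ----------
    kernel : {"polykernel", "normalized_polykernel"}
        Kernel family; see :mod:`eegattn.kernels`.
    degree : int
        Polynomial degree d.
    C : float
        Soft-margin cost parameter.
    standardize : bool
        Z-score features using training-set statistics before the kernel.
    tol : float
        SMO stopping tolerance.

    Attributes
    ----------
    classes_ : ndarray of the two label strings seen in ``fit``.
    support_vectors_ : stored training rows (on the kernel's input scale).
    dual_coef_ : signed dual coefficients (y_i * alpha_i).
    intercept_ : bias term of the decision function.
    """

    def __init__(
        self,
        kernel: str = "polykernel",
        degree: int = 2,
        C: float = 1.0,
        standardize: bool = True,
        tol: float = 1e-3,
        max_iter: int = 1_000_000,
    ):
        self.kernel = kernel
        self.degree = degree
        self.C = C
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def _kernel_spec(self) -> KernelSpec:
        return KernelSpec(kind=self.kernel, degree=self.degree)

    @staticmethod
    def _validate_X(X, n_expected: int | None = None) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[FEATURE_COLUMNS].to_numpy() if set(FEATURE_COLUMNS) <= set(X.columns) else X.to_numpy()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0, 0])
            raise ValueError(f"non-finite feature value in row {bad}")
        if n_expected is not None and X.shape[1] != n_expected:
            raise ValueError(f"expected {n_expected} features, got {X.shape[1]}")
        return X

    def fit(self, X, y=None) -> "AttentionSVC":
        if y is None:
            if isinstance(X, pd.DataFrame) and "label" in X.columns:
                y = X["label"].to_numpy()
            else:
                raise ValueError("y is required unless X is a DataFrame with a 'label' column")
        X = self._validate_X(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes, got {classes.tolist()}")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]

        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        spec = self._kernel_spec()

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        # +1 = attentive by CLASS_MAP when the labels are the canonical
        # strings; otherwise the lexicographically larger class is +1.
        if set(classes) == {ATTENTIVE, INATTENTIVE}:
            self._positive_class = ATTENTIVE
        else:
            self._positive_class = classes[-1]
        y_signed = np.where(y == self._positive_class, 1, -1)

        svc = SVC(
            kernel=spec,
            C=self.C,
            tol=self.tol,
            shrinking=True,
            cache_size=500,
            max_iter=self.max_iter,
        )
        svc.fit(Xs, y_signed)
        self._svc = svc
        self.support_ = svc.support_
        self.support_vectors_ = Xs[svc.support_]
        # libsvm orders dual_coef_ rows by its internal class order; flip so
        # coefficients are y_i * alpha_i with +1 = positive class.
        sign = 1.0 if svc.classes_[1] == 1 else -1.0
        self.dual_coef_ = sign * svc.dual_coef_[0]
        self.intercept_ = sign * float(svc.intercept_[0])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed distance-like score; positive means attentive."""
        check_is_fitted(self, "support_vectors_")
        X = self._validate_X(X, self.n_features_in_)
        Xs = (X - self.mean_) / self.scale_
        K = gram_matrix(self._kernel_spec(), Xs, self.support_vectors_)
        return K @ self.dual_coef_ + self.intercept_

    #: decision values this close to zero are ties (below SMO resolution)
    _TIE_TOL = 1e-6

    def predict(self, X) -> np.ndarray:
        """Predicted labels; a tied decision value (≈ 0) is attentive.

        The tie goes to attentive because wrongly flagging an attentive
        student as inattentive is the costlier error in classroom use.
        """
        scores = self.decision_function(X)
        neg = [c for c in self.classes_ if c != self._positive_class][0]
        return np.where(scores >= -self._TIE_TOL, self._positive_class, neg)

    # -- portable archive ---------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model to a version-tagged JSON archive."""
        check_is_fitted(self, "support_vectors_")
        payload = {
            "format_version": _ARCHIVE_VERSION,
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "positive_class": str(self._positive_class),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "AttentionSVC":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {payload.get('format_version')!r}")
        model = cls(**payload["params"])
        model.classes_ = np.array(payload["classes"])
        model._positive_class = payload["positive_class"]
        model.mean_ = np.array(payload["mean"])
        model.scale_ = np.array(payload["scale"])
        model.support_vectors_ = np.array(payload["support_vectors"])
        model.dual_coef_ = np.array(payload["dual_coef"])
        model.intercept_ = float(payload["intercept"])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model


def train_svm(
    data: pd.DataFrame,
    spec: KernelSpec | None = None,
    C: float = 1.0,
    features: list[str] | None = None,
    standardize: bool = True,
    tol: float = 1e-3,
) -> AttentionSVC:
    """Train on a feature dataset (DataFrame with a ``label`` column)."""
    spec = spec or KernelSpec()
    features = features or FEATURE_COLUMNS
    model = AttentionSVC(
        kernel=spec.kind, degree=spec.degree, C=C, standardize=standardize, tol=tol
    )
    return model.fit(data[features].to_numpy(), data["label"].to_numpy())


def predict(model: AttentionSVC, rows) -> np.ndarray:
    """Predict labels for a feature DataFrame or array of vectors."""
    if isinstance(rows, pd.DataFrame):
        rows = rows[FEATURE_COLUMNS].to_numpy()
    return model.predict(rows)
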