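"""Polynomial kernels used by the attention classifier.

Two kernels are supported, matching the usual ML-workbench naming:

* polykernel:             K(x, y) = (x·y + 1)^d
* normalized polykernel:  K(x, y) / sqrt(K(x, x) · K(y, y))

The normalized variant self-normalizes every vector to unit kernel norm,
so |K| ≤ 1 by Cauchy–Schwarz and K(x, x) = 1. Both are implemented
matrix-wise so they can be injected directly into an SMO solver as the
Gram-matrix callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KERNEL_KINDS = ("polykernel", "normalized_polykernel")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its degree."""

    kind: str = "polykernel"
    degree: int = 2

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected {KERNEL_KINDS}")
        if not (isinstance(self.degree, (int, np.integer)) and self.degree >= 1):
            raise ValueError(f"degree must be a positive integer, got {self.degree!r}")

    def __call__(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        return gram_matrix(self, X, Y)


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return X[None, :] if X.ndim == 1 else X


def polykernel(X, Y, degree: int = 2) -> np.ndarray:
    """(X·Yᵀ + 1)^degree, elementwise over all row pairs."""
    return (_as_2d(X) @ _as_2d(Y).T + 1.0) ** degree


def normalized_polykernel(X, Y, degree: int = 2) -> np.ndarray:
    """Polykernel normalized by each vector's own kernel self-value."""
    X, Y = _as_2d(X), _as_2d(Y)
    K = polykernel(X, Y, degree)
    kx = np.einsum("ij,ij->i", X, X) + 1.0
    ky = np.einsum("ij,ij->i", Y, Y) + 1.0
    return K / np.sqrt(np.outer(kx**degree, ky**degree))


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Scalar kernel value between two feature vectors."""
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} and {y.shape}")
    return float(gram_matrix(spec, x[None, :], y[None, :])[0, 0])


def gram_matrix(spec: KernelSpec, X, Y=None) -> np.ndarray:
    """Kernel matrix between the rows of X and Y (Y defaults to X)."""
    X = _as_2d(X)
    Y = X if Y is None else _as_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.kind == "polykernel":
        return polykernel(X, Y, spec.degree)
    return normalized_polykernel(X, Y, spec.degree)
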