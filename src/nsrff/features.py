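"""Trigonometric feature maps and the low-rank kernel matrices they induce.

The stationary map is Phi = [cos(X W^T) | sin(X W^T)] (n x 2m) with implied
kernel (1/m) Phi Phi^T; the nonstationary map sums the trigonometric parts
over a *pair* of frequency matrices,

    Phi = [cos(X W1^T) + cos(X W2^T) | sin(X W1^T) + sin(X W2^T)],

with implied kernel (1/4m) Phi Phi^T. The 1/4 comes from symmetrising the
product-space spectral measure over (w1, w2); with W1 == W2 every term
doubles and the construction collapses exactly onto the stationary map.

The kernel scale sigma_f^2 multiplies the kernel at the likelihood level
rather than being folded into Phi, so stationary entries stay in [-1, 1]
and nonstationary entries in [-2, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import FrequencyMatrix, FrequencyPairSet

__all__ = [
    "FeatureMap",
    "Standardizer",
    "stationary_features",
    "nonstationary_features",
    "approx_kernel_matrix",
]


@dataclass
class FeatureMap:
    """An n x 2m trigonometric design matrix with its kernel scale divisor."""

    matrix: np.ndarray
    mode: str  # "stationary" | "nonstationary"
    scale_divisor: float  # m for stationary, 4m for nonstationary

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1] // 2


@dataclass
class Standardizer:
    """Per-dimension z-score transform fitted on training inputs.

    Standardising before featurisation makes frequency magnitudes
    comparable across covariates with different natural units; the fitted
    constants are stored so prediction locations receive the identical
    transform.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, float))
        std = X.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)  # constant columns pass through
        return cls(mean=X.mean(axis=0), std=std)

    @classmethod
    def identity(cls, D: int) -> "Standardizer":
        return cls(mean=np.zeros(D), std=np.ones(D))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.std


def _angles(X: np.ndarray, omega: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    omega = np.atleast_2d(np.asarray(omega, float))
    if X.shape[1] != omega.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match frequency dimension {omega.shape[1]}"
        )
    return X @ omega.T


def stationary_features(X: np.ndarray, omega: FrequencyMatrix | np.ndarray) -> FeatureMap:
    """Build the stationary map [cos(X W^T) | sin(X W^T)], shape n x 2m."""
    W = omega.entries if isinstance(omega, FrequencyMatrix) else omega
    T = _angles(X, W)
    return FeatureMap(
        matrix=np.hstack([np.cos(T), np.sin(T)]),
        mode="stationary",
        scale_divisor=float(np.atleast_2d(W).shape[0]),
    )


def nonstationary_features(X: np.ndarray, pair: FrequencyPairSet) -> FeatureMap:
    """Build the paired-frequency map with scale divisor 4m."""
    T1 = _angles(X, pair.omega1.entries)
    T2 = _angles(X, pair.omega2.entries)
    return FeatureMap(
        matrix=np.hstack([np.cos(T1) + np.cos(T2), np.sin(T1) + np.sin(T2)]),
        mode="nonstationary",
        scale_divisor=4.0 * pair.m,
    )


def approx_kernel_matrix(
    phi: FeatureMap, phi2: FeatureMap | None = None, sigma_f2: float = 1.0
) -> np.ndarray:
    """Monte-Carlo kernel matrix sigma_f^2 / s * Phi Phi2^T.

    With ``phi2 is None`` (or the same object) the result is a symmetric
    PSD Gram matrix whose stationary diagonal is exactly sigma_f^2.
    """
    other = phi if phi2 is None else phi2
    if other.mode != phi.mode or other.scale_divisor != phi.scale_divisor:
        raise ValueError("feature maps must share mode and scale divisor")
    K = (sigma_f2 / phi.scale_divisor) * (phi.matrix @ other.matrix.T)
    if other is phi:
        K = 0.5 * (K + K.T)
    return K
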