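"""Reduced-rank Gaussian process regression on trigonometric features.

With an n x 2m feature map Phi, scale divisor s and kernel matrix
K = (sigma_f^2/s) Phi Phi^T, all GP quantities reduce (via the Woodbury and
determinant lemmas) to solves against the 2m x 2m matrix

    A = Phi^T Phi + (s * sigma_n^2 / sigma_f^2) * I.

Writing R = chol(A), R a1 = Phi^T y, R^T a2 = a1 (so a2 = A^{-1} Phi^T y),
the log marginal likelihood is

    log p(y) = -(||y||^2 - ||a1||^2) / (2 sigma_n^2) - sum_i log R_ii
               + m log(s sigma_n^2 / sigma_f^2) - (n/2) log(2 pi sigma_n^2)

and the posterior predictive at a new feature row phi* is

    mean = phi*^T a2,    var = sigma_n^2 (1 + phi*^T A^{-1} phi*),

which agree exactly with the dense O(n^3) predictive equations under K
(the dense path is kept here as a verification oracle). Cost is O(n m^2)
time and O(n m) memory, so m << n gives large savings over the dense GP.

Gradients of the log marginal likelihood with respect to the frequencies
and the log hyperparameters are computed in closed form (see
`lml_value_and_grad`), which is what makes frequency learning by gradient
ascent practical without automatic differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .features import (
    FeatureMap,
    Standardizer,
    nonstationary_features,
    stationary_features,
)
from .spectral import FrequencyMatrix, FrequencyPairSet

__all__ = [
    "Hyperparameters",
    "GPFit",
    "PredictiveDistribution",
    "log_marginal_likelihood",
    "fit",
    "fit_gp",
    "predict",
    "predict_features",
    "dense_gp_oracle",
    "lml_value_and_grad",
]


@dataclass
class Hyperparameters:
    """Observation noise variance and kernel scale variance.

    Both are variances (squared units of y). They are optimised on the log
    scale to keep them positive. ``sigma_f2 == 0`` is accepted as the
    degenerate no-signal limit (prior collapses to pure noise).
    """

    sigma_n2: float
    sigma_f2: float

    def __post_init__(self) -> None:
        if not (self.sigma_n2 > 0):
            raise ValueError("sigma_n2 must be strictly positive")
        if self.sigma_f2 < 0:
            raise ValueError("sigma_f2 must be nonnegative")


@dataclass
class PredictiveDistribution:
    """Per-location Gaussian posterior predictive (includes observation noise)."""

    mean: np.ndarray
    variance: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.variance)


@dataclass
class GPFit:
    """Cholesky factor and solve vectors of a fitted reduced-rank GP."""

    R: np.ndarray  # lower-triangular chol factor of A, 2m x 2m
    alpha1: np.ndarray
    alpha2: np.ndarray
    hp: Hyperparameters
    mode: str
    scale_divisor: float
    frequencies: FrequencyMatrix | FrequencyPairSet | None = None
    standardizer: Standardizer | None = None


def _chol_jitter(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky with an escalating jitter ladder (3 attempts)."""
    base = 1e-10 * np.trace(A) / A.shape[0]
    jitter = 0.0
    for attempt in range(4):
        try:
            return cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = base * 10.0**attempt if base > 0 else 10.0 ** (attempt - 12)
    raise np.linalg.LinAlgError("matrix not positive definite even after jitter")


def _iid_noise_lml(y: np.ndarray, sigma_n2: float) -> float:
    n = y.size
    return float(-0.5 * np.dot(y, y) / sigma_n2 - 0.5 * n * np.log(2 * np.pi * sigma_n2))


def _build_A(phi: FeatureMap, hp: Hyperparameters) -> np.ndarray:
    ridge = phi.scale_divisor * hp.sigma_n2 / hp.sigma_f2
    A = phi.matrix.T @ phi.matrix
    A[np.diag_indices_from(A)] += ridge
    return A


def log_marginal_likelihood(phi: FeatureMap, y: np.ndarray, hp: Hyperparameters) -> float:
    """Evaluate log p(y | frequencies, hyperparameters) in O(n m^2)."""
    y = np.asarray(y, float).ravel()
    n, m = phi.n, phi.m
    if y.size != n:
        raise ValueError("y length must match feature map rows")
    if hp.sigma_f2 == 0.0:
        return _iid_noise_lml(y, hp.sigma_n2)
    R = _chol_jitter(_build_A(phi, hp))
    alpha1 = solve_triangular(R, phi.matrix.T @ y, lower=True)
    ridge = phi.scale_divisor * hp.sigma_n2 / hp.sigma_f2
    return float(
        -(np.dot(y, y) - np.dot(alpha1, alpha1)) / (2 * hp.sigma_n2)
        - np.sum(np.log(np.diag(R)))
        + m * np.log(ridge)
        - 0.5 * n * np.log(2 * np.pi * hp.sigma_n2)
    )


def fit(
    phi: FeatureMap,
    y: np.ndarray,
    hp: Hyperparameters,
    frequencies: FrequencyMatrix | FrequencyPairSet | None = None,
    standardizer: Standardizer | None = None,
) -> GPFit:
    """Factorise A and precompute the solve vectors used for prediction."""
    y = np.asarray(y, float).ravel()
    if y.size != phi.n:
        raise ValueError("y length must match feature map rows")
    if hp.sigma_f2 == 0.0:
        k2 = phi.matrix.shape[1]
        return GPFit(
            R=np.diag(np.full(k2, np.inf)),  # never solved against; see predict_features
            alpha1=np.zeros(k2),
            alpha2=np.zeros(k2),
            hp=hp,
            mode=phi.mode,
            scale_divisor=phi.scale_divisor,
            frequencies=frequencies,
            standardizer=standardizer,
        )
    R = _chol_jitter(_build_A(phi, hp))
    alpha1 = solve_triangular(R, phi.matrix.T @ y, lower=True)
    alpha2 = solve_triangular(R.T, alpha1, lower=False)
    return GPFit(
        R=R,
        alpha1=alpha1,
        alpha2=alpha2,
        hp=hp,
        mode=phi.mode,
        scale_divisor=phi.scale_divisor,
        frequencies=frequencies,
        standardizer=standardizer,
    )


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    frequencies: FrequencyMatrix | FrequencyPairSet,
    hp: Hyperparameters,
    standardize: bool = True,
) -> GPFit:
    """Convenience wrapper: standardise X, featurise, and fit."""
    X = np.atleast_2d(np.asarray(X, float))
    std = Standardizer.fit(X) if standardize else Standardizer.identity(X.shape[1])
    Xs = std.transform(X)
    if isinstance(frequencies, FrequencyPairSet):
        phi = nonstationary_features(Xs, frequencies)
    else:
        phi = stationary_features(Xs, frequencies)
    return fit(phi, y, hp, frequencies=frequencies, standardizer=std)


def _featurise_like(fitted: GPFit, Xstar: np.ndarray) -> FeatureMap:
    if fitted.frequencies is None:
        raise ValueError("fit carries no frequencies; use predict_features instead")
    Xs = Xstar if fitted.standardizer is None else fitted.standardizer.transform(Xstar)
    if isinstance(fitted.frequencies, FrequencyPairSet):
        return nonstationary_features(Xs, fitted.frequencies)
    return stationary_features(Xs, fitted.frequencies)


def predict_features(fitted: GPFit, phi_star: FeatureMap) -> PredictiveDistribution:
    """Posterior predictive at pre-built feature rows."""
    if phi_star.mode != fitted.mode:
        raise ValueError("feature map mode does not match the fitted model")
    P = phi_star.matrix
    if fitted.hp.sigma_f2 == 0.0:
        return PredictiveDistribution(
            mean=np.zeros(P.shape[0]),
            variance=np.full(P.shape[0], fitted.hp.sigma_n2),
        )
    mean = P @ fitted.alpha2
    alpha3 = solve_triangular(fitted.R, P.T, lower=True)
    variance = fitted.hp.sigma_n2 * (1.0 + np.sum(alpha3**2, axis=0))
    return PredictiveDistribution(mean=mean, variance=variance)


def predict(fitted: GPFit, Xstar: np.ndarray) -> PredictiveDistribution:
    """Posterior predictive mean and variance at new locations.

    Locations are passed through the stored standardiser and featurised
    with the stored frequencies; the variance includes the observation
    noise floor sigma_n^2.
    """
    return predict_features(fitted, _featurise_like(fitted, np.atleast_2d(np.asarray(Xstar, float))))


def dense_gp_oracle(
    K: np.ndarray,
    y: np.ndarray,
    sigma_n2: float,
    Kstar: np.ndarray | None = None,
    kstarstar: np.ndarray | None = None,
):
    """Direct O(n^3) GP regression; testing-only reference path.

    Returns (log marginal likelihood, predictive means, predictive
    variances); the predictive pieces are None when Kstar is omitted.
    Variances include the observation noise, matching `predict`.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    C = np.asarray(K, float) + sigma_n2 * np.eye(n)
    L = _chol_jitter(C)
    z = solve_triangular(L, y, lower=True)
    lml = float(-0.5 * np.dot(z, z) - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi))
    means = variances = None
    if Kstar is not None:
        Kstar = np.atleast_2d(np.asarray(Kstar, float))
        means = Kstar @ cho_solve((L, True), y)
        V = solve_triangular(L, Kstar.T, lower=True)
        variances = sigma_n2 + np.asarray(kstarstar, float) - np.sum(V**2, axis=0)
    return lml, means, variances


def lml_value_and_grad(
    Xs: np.ndarray,
    y: np.ndarray,
    omega1: np.ndarray,
    omega2: np.ndarray | None,
    log_sigma_n2: float,
    log_sigma_f2: float,
):
    """Log marginal likelihood and its closed-form gradients.

    Parameters are the frequency matrices (omega2 is None in stationary
    mode) and the *log* hyperparameters. Inputs Xs are assumed already
    standardised. Returns ``(lml, grad)`` with ``grad`` a dict holding
    ``omega1``, ``omega2`` (None in stationary mode), ``log_sigma_n2``,
    ``log_sigma_f2``.

    Derivation sketch: with A = Phi^T Phi + r I, r = s sigma_n^2/sigma_f^2
    and beta = A^{-1} Phi^T y,

        dL/dPhi = (y - Phi beta) beta^T / sigma_n^2 - Phi A^{-1}

    which is chained through the cos/sin entries onto the frequency
    matrices; the hyperparameter gradients collect the direct sigma_n^2
    terms plus the ridge path dL/dr with
    dL/dr = -||beta||^2/(2 sigma_n^2) - tr(A^{-1})/2 + m/r.
    """
    Xs = np.atleast_2d(np.asarray(Xs, float))
    y = np.asarray(y, float).ravel()
    n = y.size
    sigma_n2 = float(np.exp(log_sigma_n2))
    sigma_f2 = float(np.exp(log_sigma_f2))
    stationary = omega2 is None
    m = np.atleast_2d(omega1).shape[0]
    s = float(m) if stationary else 4.0 * m

    T1 = Xs @ np.atleast_2d(omega1).T
    if stationary:
        C, S = np.cos(T1), np.sin(T1)
    else:
        T2 = Xs @ np.atleast_2d(omega2).T
        C, S = np.cos(T1) + np.cos(T2), np.sin(T1) + np.sin(T2)
    Phi = np.hstack([C, S])

    r = s * sigma_n2 / sigma_f2
    A = Phi.T @ Phi
    A[np.diag_indices_from(A)] += r
    R = _chol_jitter(A)
    alpha1 = solve_triangular(R, Phi.T @ y, lower=True)
    beta = solve_triangular(R.T, alpha1, lower=False)
    q = float(np.dot(alpha1, alpha1))
    yy = float(np.dot(y, y))

    lml = (
        -(yy - q) / (2 * sigma_n2)
        - float(np.sum(np.log(np.diag(R))))
        + m * np.log(r)
        - 0.5 * n * np.log(2 * np.pi * sigma_n2)
    )

    Ainv = cho_solve((R, True), np.eye(2 * m))
    resid = y - Phi @ beta
    G = np.outer(resid, beta) / sigma_n2 - Phi @ Ainv
    Gc, Gs = G[:, :m], G[:, m:]

    def chain(T):
        dT = -Gc * np.sin(T) + Gs * np.cos(T)
        return dT.T @ Xs

    if stationary:
        d_omega1, d_omega2 = chain(T1), None
    else:
        d_omega1, d_omega2 = chain(T1), chain(T2)

    dL_dr = -float(np.dot(beta, beta)) / (2 * sigma_n2) - 0.5 * float(np.trace(Ainv)) + m / r
    d_log_sn2 = (yy - q) / (2 * sigma_n2) - 0.5 * n + r * dL_dr
    d_log_sf2 = -r * dL_dr

    grad = {
        "omega1": d_omega1,
        "omega2": d_omega2,
        "log_sigma_n2": d_log_sn2,
        "log_sigma_f2": d_log_sf2,
    }
    return float(lml), grad
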