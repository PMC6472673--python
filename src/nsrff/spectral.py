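"""Spectral measures for random Fourier feature kernels.

A stationary kernel is the Fourier transform of a nonnegative spectral
measure (Bochner); a nonstationary kernel is characterised by a measure on
the *product* frequency space R^D x R^D (Yaglom-type generalisation).
This module samples frequency matrices from the classical stationary
families (squared-exponential, Laplacian/exponential, Matern-like
Student-t) and composes them into nonstationary measures through
per-dimension products, Gaussian copulas and Gaussian mixtures.

Each family is defined operationally by its sampling distribution: the
kernel it induces is the characteristic function E[cos(w^T d)] of that
distribution, estimated by Monte Carlo through the feature map. For the
Gaussian family with per-dimension lengthscales l_d, frequencies are drawn
N(0, diag(1/l_d^2)) so the implied kernel is the ARD squared exponential
exp(-0.5 * sum_d (d_d/l_d)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpectralSpec",
    "FrequencyMatrix",
    "FrequencyPairSet",
    "sample_frequencies",
    "sample_frequency_pair",
    "sample_product_measure",
    "gaussian_copula_transform",
    "sample_mixture",
]

_FAMILIES = {"gaussian", "laplacian_cauchy", "matern_t", "mixture", "copula"}


@dataclass
class SpectralSpec:
    """Description of a sampling distribution over frequencies.

    Parameters
    ----------
    family:
        One of ``gaussian``, ``laplacian_cauchy``, ``matern_t``,
        ``mixture``, ``copula``.
    dim:
        Input dimension D; sampled frequency rows live in R^D.
    lengthscales:
        Per-dimension lengthscales l_d > 0 for the gaussian,
        laplacian_cauchy and matern_t families. A scalar broadcasts.
        Frequencies scale as 1/l_d, so large lengthscales give slowly
        varying kernels.
    df:
        Degrees of freedom lambda > 0 of the matern_t family (Student-t
        frequencies; heavier tails = rougher implied kernel).
    weights, means, covariances:
        Gaussian-mixture components (mixture family). Weights lie on the
        simplex; each mean is length D and each covariance D x D.
    corr:
        D x D correlation matrix (unit diagonal, symmetric positive
        definite) of the latent Gaussian in the copula family.
    marginals:
        Per-dimension target marginals for the copula family: each entry
        is either a scipy.stats frozen distribution or a callable quantile
        function u in (0,1) -> R.
    """

    family: str
    dim: int
    lengthscales: np.ndarray | float | None = None
    df: float | None = None
    weights: np.ndarray | None = None
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    corr: np.ndarray | None = None
    marginals: Sequence | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown spectral family {self.family!r}")
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if self.family in ("gaussian", "laplacian_cauchy", "matern_t"):
            ls = np.broadcast_to(
                np.asarray(1.0 if self.lengthscales is None else self.lengthscales, float),
                (self.dim,),
            ).copy()
            if np.any(ls <= 0) or not np.all(np.isfinite(ls)):
                raise ValueError("lengthscales must be strictly positive and finite")
            self.lengthscales = ls
        if self.family == "matern_t":
            if self.df is None or self.df <= 0:
                raise ValueError("matern_t requires degrees of freedom df > 0")
        if self.family == "mixture":
            w = np.asarray(self.weights, float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must be nonnegative and sum to 1")
            self.weights = w
            self.means = np.atleast_2d(np.asarray(self.means, float))
            covs = np.asarray(self.covariances, float)
            if covs.ndim == 2:
                covs = np.broadcast_to(covs, (len(w),) + covs.shape).copy()
            self.covariances = covs
            if self.means.shape != (len(w), self.dim):
                raise ValueError("mixture means must have shape (n_components, dim)")
        if self.family == "copula":
            S = np.asarray(self.corr, float)
            if S.shape != (self.dim, self.dim) or not np.allclose(S, S.T):
                raise ValueError("corr must be a symmetric D x D matrix")
            if not np.allclose(np.diag(S), 1.0):
                raise ValueError("corr must have unit diagonal")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("corr must be positive definite")
            self.corr = S
            if self.marginals is None or len(self.marginals) != self.dim:
                raise ValueError("copula requires one target marginal per dimension")

    # -- serialisation (run-config dialect) ---------------------------------
    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "dim": self.dim}
        if self.family in ("gaussian", "laplacian_cauchy", "matern_t"):
            d["lengthscales"] = np.asarray(self.lengthscales).tolist()
        if self.family == "matern_t":
            d["df"] = float(self.df)
        if self.family == "mixture":
            d["weights"] = self.weights.tolist()
            d["means"] = self.means.tolist()
            d["covariances"] = self.covariances.tolist()
        if self.family == "copula":
            raise ValueError("copula specs with callable marginals are not serialisable")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralSpec":
        kw = dict(d)
        for key in ("lengthscales", "weights", "means", "covariances", "corr"):
            if key in kw and kw[key] is not None:
                kw[key] = np.asarray(kw[key], float)
        return cls(**kw)


@dataclass
class FrequencyMatrix:
    """An m x D matrix whose rows are sampled (or learned) frequencies."""

    entries: np.ndarray
    provenance: str = "sampled"

    def __post_init__(self) -> None:
        self.entries = np.atleast_2d(np.asarray(self.entries, float))
        if self.entries.shape[0] < 1:
            raise ValueError("a frequency matrix needs at least one row")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("frequency entries must be finite")

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def dim(self) -> int:
        return self.entries.shape[1]


@dataclass
class FrequencyPairSet:
    """The paired frequency sample {(w1_k, w2_k)} of a nonstationary kernel.

    Equal pairs (omega1 == omega2) collapse the product measure onto the
    diagonal and recover a stationary kernel.
    """

    omega1: FrequencyMatrix
    omega2: FrequencyMatrix

    def __post_init__(self) -> None:
        if self.omega1.entries.shape != self.omega2.entries.shape:
            raise ValueError("omega1 and omega2 must have identical shape")

    @property
    def m(self) -> int:
        return self.omega1.m

    @property
    def dim(self) -> int:
        return self.omega1.dim


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_entries(spec: SpectralSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "gaussian":
        return rng.standard_normal((m, spec.dim)) / spec.lengthscales
    if spec.family == "laplacian_cauchy":
        # independent per-dimension Cauchy: implied kernel prod_d exp(-|d_d|/l_d)
        return rng.standard_cauchy((m, spec.dim)) / spec.lengthscales
    if spec.family == "matern_t":
        # multivariate t via Gaussian / chi-square scale mixture
        z = rng.standard_normal((m, spec.dim))
        g = rng.chisquare(spec.df, size=m)
        return z * np.sqrt(spec.df / g)[:, None] / spec.lengthscales
    if spec.family == "mixture":
        return _mixture_entries(spec.weights, spec.means, spec.covariances, m, rng)
    if spec.family == "copula":
        base = rng.multivariate_normal(np.zeros(spec.dim), spec.corr, size=m)
        return _copula_entries(base, spec.marginals)
    raise ValueError(f"unknown spectral family {spec.family!r}")  # pragma: no cover


def sample_frequencies(spec: SpectralSpec, m: int, seed) -> FrequencyMatrix:
    """Draw m i.i.d. frequencies from the spectral density named by `spec`.

    The same (spec, m, seed) triple reproduces the sample bit-for-bit.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    entries = _sample_entries(spec, m, _rng(seed))
    return FrequencyMatrix(entries, provenance=spec.family)


def sample_frequency_pair(spec: SpectralSpec, m: int, seed) -> FrequencyPairSet:
    """Draw omega1 and omega2 independently from the same spec.

    Independent draws place mass off the diagonal of the product frequency
    space, giving a genuinely nonstationary kernel; this is the standard
    initialisation for frequency learning.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s1, s2 = ss.spawn(2)
    return FrequencyPairSet(
        sample_frequencies(spec, m, np.random.default_rng(s1)),
        sample_frequencies(spec, m, np.random.default_rng(s2)),
    )


def sample_product_measure(
    per_dim_specs: Sequence[SpectralSpec], m: int, seed
) -> FrequencyPairSet:
    """Sample a separable nonstationary measure, one 1-D spec per dimension.

    Columns of omega1 and omega2 are drawn independently across dimensions
    and between the two matrices, so the implied kernel factorises into a
    product of per-dimension (nonstationary) kernels.
    """
    for spec in per_dim_specs:
        if spec.dim != 1:
            raise ValueError("product measure requires one-dimensional specs")
    D = len(per_dim_specs)
    if D < 1:
        raise ValueError("need at least one per-dimension spec")
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(2 * D)
    cols1 = [
        sample_frequencies(spec, m, np.random.default_rng(subs[2 * d])).entries[:, 0]
        for d, spec in enumerate(per_dim_specs)
    ]
    cols2 = [
        sample_frequencies(spec, m, np.random.default_rng(subs[2 * d + 1])).entries[:, 0]
        for d, spec in enumerate(per_dim_specs)
    ]
    return FrequencyPairSet(
        FrequencyMatrix(np.column_stack(cols1), provenance="product"),
        FrequencyMatrix(np.column_stack(cols2), provenance="product"),
    )


def _quantile(marginal) -> Callable[[np.ndarray], np.ndarray]:
    if callable(getattr(marginal, "ppf", None)):
        return marginal.ppf
    if callable(marginal):
        return marginal
    raise TypeError("marginal must be a frozen distribution or a quantile callable")


def _copula_entries(base: np.ndarray, marginals: Sequence) -> np.ndarray:
    u = stats.norm.cdf(base)
    out = np.empty_like(base)
    for d in range(base.shape[1]):
        q = _quantile(marginals[d])
        col = np.asarray(q(u[:, d]), float)
        du = q(np.array([0.25, 0.75]))
        if not du[1] >= du[0]:
            raise ValueError("quantile functions must be monotone nondecreasing")
        out[:, d] = col
    return out


def gaussian_copula_transform(freqs: FrequencyMatrix, target_marginals: Sequence) -> FrequencyMatrix:
    """Push standard-Gaussian columns through a Gaussian copula.

    Each column z_d (marginally N(0,1), jointly N(0, Sigma)) is mapped to
    Q_d(Phi(z_d)) where Phi is the standard normal CDF and Q_d the target
    quantile function, so the output keeps the Gaussian dependence while
    acquiring the requested marginals.
    """
    if len(target_marginals) != freqs.dim:
        raise ValueError("need one target marginal per dimension")
    return FrequencyMatrix(_copula_entries(freqs.entries, target_marginals), provenance="copula")


def _mixture_entries(weights, means, covariances, m, rng) -> np.ndarray:
    k = len(weights)
    D = means.shape[1]
    labels = rng.choice(k, size=m, p=weights)
    out = np.empty((m, D))
    for j in range(k):
        idx = np.flatnonzero(labels == j)
        if idx.size:
            out[idx] = rng.multivariate_normal(means[j], covariances[j], size=idx.size)
    return out


def sample_mixture(
    components: Sequence[tuple[np.ndarray, np.ndarray]],
    weights: Sequence[float],
    m: int,
    seed,
) -> FrequencyMatrix:
    """Draw frequencies from a Gaussian mixture sum_j w_j N(mu_j, C_j).

    ``components`` is a sequence of (mean, covariance) pairs. Mixtures of
    Gaussians are dense in the space of spectral densities, so this family
    can approximate arbitrarily complex (non-separable) kernels.
    """
    w = np.asarray(weights, float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    means = np.atleast_2d(np.asarray([c[0] for c in components], float))
    covs = np.asarray([np.atleast_2d(np.asarray(c[1], float)) for c in components])
    entries = _mixture_entries(w, means, covs, m, _rng(seed))
    return FrequencyMatrix(entries, provenance="mixture")
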