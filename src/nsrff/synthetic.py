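"""Synthetic datasets with known generating covariance.

Every generator is a pure function of (parameters, seed) and returns the
ground truth alongside the data, so kernel recovery, calibration and
stationary-vs-nonstationary comparisons can all be tested without any
external data. Three flavours are provided:

* exact GP draws from a frequency-defined (stationary or paired-frequency
  nonstationary) kernel — the model's own covariance family, used for
  well-specified recovery and calibration checks;
* warped-input fields — a stationary GP composed with a smooth monotone
  input distortion, giving a location-dependent effective lengthscale the
  way real temperature surfaces do;
* trend series — 1-D series whose smoothness changes between segments,
  emulating financial series with regime-dependent roughness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky

from .features import FeatureMap, approx_kernel_matrix, nonstationary_features, stationary_features
from .spectral import FrequencyMatrix, FrequencyPairSet

__all__ = [
    "SyntheticDataset",
    "gen_from_frequency_kernel",
    "gen_warped_field",
    "gen_trend_series",
    "uniform_design",
    "grid_design",
]


@dataclass
class SyntheticDataset:
    """Inputs, responses and the generating-process description."""

    X: np.ndarray
    y: np.ndarray
    truth: dict
    seed: int

    def to_csv(self, path) -> None:
        import pandas as pd

        D = self.X.shape[1]
        df = pd.DataFrame(self.X, columns=[f"x{d + 1}" for d in range(D)])
        df["y"] = self.y
        df.to_csv(path, index=False)

    def truth_to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o).__name__)

        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **self.truth}, fh, indent=2, default=default)


def uniform_design(n: int, D: int, rng) -> np.ndarray:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(0.0, 1.0, size=(n, D))


def grid_design(n_per_side: int, D: int) -> np.ndarray:
    axes = [np.linspace(0.0, 1.0, n_per_side)] * D
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([g.ravel() for g in mesh])


def _mvn_draw(cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    L = cholesky(cov + 1e-12 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0]), lower=True)
    return L @ rng.standard_normal(cov.shape[0])


def gen_from_frequency_kernel(
    X: np.ndarray,
    frequencies: FrequencyMatrix | FrequencyPairSet,
    sigma_f2: float,
    sigma_n2: float,
    seed: int,
) -> SyntheticDataset:
    """Draw y ~ N(0, sigma_f^2 K + sigma_n^2 I) with K the feature-map kernel.

    The covariance receives a 1e-8 * sigma_f^2 diagonal jitter before
    factorisation. sigma_f2 = 0 yields pure i.i.d. noise.
    """
    X = np.atleast_2d(np.asarray(X, float))
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if isinstance(frequencies, FrequencyPairSet):
        phi = nonstationary_features(X, frequencies)
        truth_freqs = {
            "omega1": frequencies.omega1.entries,
            "omega2": frequencies.omega2.entries,
        }
        mode = "nonstationary"
    else:
        phi = stationary_features(X, frequencies)
        truth_freqs = {"omega": frequencies.entries}
        mode = "stationary"
    if sigma_f2 == 0.0:
        y = np.sqrt(sigma_n2) * rng.standard_normal(n)
    else:
        K = approx_kernel_matrix(phi, sigma_f2=sigma_f2)
        C = K + (sigma_n2 + 1e-8 * sigma_f2) * np.eye(n)
        y = _mvn_draw(C, rng)
    truth = {
        "kind": "frequency_kernel",
        "mode": mode,
        "sigma_f2": sigma_f2,
        "sigma_n2": sigma_n2,
        **truth_freqs,
    }
    return SyntheticDataset(X=X, y=y, truth=truth, seed=seed)


def _se_kernel(A: np.ndarray, B: np.ndarray, lengthscale: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-0.5 * d2 / lengthscale**2)


def _exp_warp(X: np.ndarray, strength: float) -> np.ndarray:
    # monotone [0,1] -> [0,1] distortion; identity at strength 0; the local
    # derivative (hence effective lengthscale) varies by a factor e^strength
    if strength == 0:
        return X
    return (np.expm1(strength * X)) / np.expm1(strength)


def gen_warped_field(
    n: int,
    warp_strength: float,
    lengthscale: float = 0.2,
    sigma_n2: float = 0.01,
    seed: int = 0,
    D: int = 2,
    grid: bool = False,
) -> SyntheticDataset:
    """Nonstationary field y = f(w(x)) + noise, f a stationary SE-GP draw.

    ``warp_strength`` controls how strongly the effective lengthscale
    varies across the domain (0 = stationary).
    """
    rng = np.random.default_rng(seed)
    if grid:
        side = int(np.ceil(n ** (1.0 / D)))
        X = grid_design(side, D)[:n]
    else:
        X = rng.uniform(0.0, 1.0, size=(n, D))
    W = _exp_warp(X, warp_strength)
    K = _se_kernel(W, W, lengthscale)
    f = _mvn_draw(K + 1e-10 * np.eye(len(W)), rng)
    y = f + np.sqrt(sigma_n2) * rng.standard_normal(n)
    truth = {
        "kind": "warped_field",
        "warp_strength": warp_strength,
        "lengthscale": lengthscale,
        "sigma_n2": sigma_n2,
    }
    return SyntheticDataset(X=X, y=y, truth=truth, seed=seed)


def gen_trend_series(
    n: int,
    lengthscales: Sequence[float] = (0.2, 0.02),
    sigma_n2: float = 1e-4,
    seed: int = 0,
    drift: float = 1.0,
) -> SyntheticDataset:
    """1-D series with piecewise smoothness plus linear drift.

    The domain [0,1] is split into len(lengthscales) equal segments; each
    segment is an SE-GP draw with its own lengthscale, offset to join the
    previous segment continuously, emulating series whose roughness
    changes over time (log stock prices being the canonical example).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n)[:, None]
    bounds = np.array_split(np.arange(n), len(lengthscales))
    y = np.empty(n)
    level = 0.0
    for idx, ls in zip(bounds, lengthscales):
        seg_x = x[idx]
        K = _se_kernel(seg_x, seg_x, ls)
        f = _mvn_draw(K + 1e-10 * np.eye(len(idx)), rng)
        f = f - f[0] + level
        y[idx] = f
        level = f[-1]
    y = y + drift * x[:, 0] + np.sqrt(sigma_n2) * rng.standard_normal(n)
    truth = {
        "kind": "trend_series",
        "lengthscales": list(lengthscales),
        "sigma_n2": sigma_n2,
        "drift": drift,
    }
    return SyntheticDataset(X=x, y=y, truth=truth, seed=seed)
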