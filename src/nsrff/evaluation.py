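"""Accuracy and calibration scoring for Gaussian predictive distributions.

Point accuracy is mean squared error and Pearson correlation; probabilistic
calibration uses the continuous ranked probability score (CRPS, closed
Gaussian form) and the probability integral transform (PIT). A calibrated
model has PIT values approximately Uniform(0,1) and small CRPS.

The cross-validation harness mirrors the standard protocol for this kind
of model: random 70/30 train/test splits, the *full* training procedure on
each 70% (including its internal early-stopping split), scores on the held
out 30%, averaged over independent runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

from .inference import predict
from .training import TrainingConfig, train

__all__ = ["ScoreReport", "crps_gaussian", "pit", "point_scores", "cross_validate"]

_INV_SQRT_PI = 1.0 / np.sqrt(np.pi)


@dataclass
class ScoreReport:
    """Aggregate and per-run accuracy / calibration scores."""

    mse: float
    pearson_correlation: float
    mean_crps: float
    crps: np.ndarray = field(default_factory=lambda: np.empty(0))
    pit_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_run: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "pearson_correlation": self.pearson_correlation,
            "mean_crps": self.mean_crps,
            "crps": np.asarray(self.crps).tolist(),
            "pit_values": np.asarray(self.pit_values).tolist(),
            "per_run": self.per_run,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_histograms(self, pit_path, crps_path, bins: int = 20) -> None:
        """Write PIT and CRPS histogram tables as CSV (bin_left, bin_right, count)."""
        import pandas as pd

        for values, path, rng in (
            (self.pit_values, pit_path, (0.0, 1.0)),
            (self.crps, crps_path, None),
        ):
            counts, edges = np.histogram(np.asarray(values), bins=bins, range=rng)
            pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            ).to_csv(path, index=False)


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return sigma


def crps_gaussian(mu, sigma, y) -> np.ndarray:
    """Closed-form CRPS of N(mu, sigma^2) against observation y.

    CRPS = sigma * [z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi)], z = (y-mu)/sigma.
    Nonnegative; reduces to |y - mu| as sigma -> 0. Lower is better, and it
    is a strictly proper score: the data-generating distribution minimises
    it in expectation.
    """
    sigma = _check_sigma(sigma)
    mu, y = np.asarray(mu, float), np.asarray(y, float)
    z = (y - mu) / sigma
    return sigma * (z * (2 * stats.norm.cdf(z) - 1) + 2 * stats.norm.pdf(z) - _INV_SQRT_PI)


def pit(mu, sigma, y) -> np.ndarray:
    """Probability integral transform Phi((y - mu)/sigma), in [0, 1]."""
    sigma = _check_sigma(sigma)
    return stats.norm.cdf((np.asarray(y, float) - np.asarray(mu, float)) / sigma)


def point_scores(predictions, y) -> tuple[float, float]:
    """(MSE, Pearson correlation). Correlation is NaN for constant inputs."""
    p = np.asarray(predictions, float).ravel()
    t = np.asarray(y, float).ravel()
    if p.size != t.size:
        raise ValueError("predictions and y must have equal length")
    mse = float(np.mean((p - t) ** 2))
    if p.size < 2 or np.all(p == p[0]) or np.all(t == t[0]):
        return mse, float("nan")
    return mse, float(np.corrcoef(p, t)[0, 1])


def cross_validate(
    dataset,
    config: TrainingConfig,
    n_runs: int = 20,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> ScoreReport:
    """Repeated random-split evaluation of the full training procedure.

    Each run draws an independent 70/30 (by default) split from a
    run-indexed substream of ``seed``, trains on the larger part and
    scores MSE, correlation, CRPS and PIT on the smaller. Aggregates are
    means over runs (PIT/CRPS values are pooled).
    """
    if hasattr(dataset, "X") and hasattr(dataset, "y"):
        X, y = np.atleast_2d(np.asarray(dataset.X, float)), np.asarray(dataset.y, float).ravel()
    else:
        X, y = dataset
        X, y = np.atleast_2d(np.asarray(X, float)), np.asarray(y, float).ravel()

    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(n_runs)
    per_run = []
    all_crps, all_pit = [], []
    for run, sub in enumerate(subs):
        run_seed = int(sub.generate_state(1)[0] % (2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=train_fraction, random_state=run_seed
        )
        if len(ytr) == 0 or len(yte) == 0:
            raise ValueError("degenerate cross-validation split")
        model = train((Xtr, ytr), replace(config, seed=run_seed))
        pred = predict(model.gpfit, Xte)
        mse, corr = point_scores(pred.mean, yte)
        c = crps_gaussian(pred.mean, pred.sd, yte)
        u = pit(pred.mean, pred.sd, yte)
        per_run.append(
            {"run": run, "mse": mse, "pearson_correlation": corr, "mean_crps": float(np.mean(c))}
        )
        all_crps.append(c)
        all_pit.append(u)

    crps_all = np.concatenate(all_crps)
    pit_all = np.concatenate(all_pit)
    corrs = [r["pearson_correlation"] for r in per_run]
    return ScoreReport(
        mse=float(np.mean([r["mse"] for r in per_run])),
        pearson_correlation=float(np.nanmean(corrs)) if np.any(np.isfinite(corrs)) else float("nan"),
        mean_crps=float(np.mean(crps_all)),
        crps=crps_all,
        pit_values=pit_all,
        per_run=per_run,
    )
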