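"""Frequency learning by marginal-likelihood gradient ascent.

The frequencies of the trigonometric feature map are treated as kernel
parameters and optimised jointly with the log noise/scale variances by
ADAM on the negative log marginal likelihood. Two regularisers guard the
heavily over-parameterised kernel against overfitting:

* Gaussian dropout — each gradient step evaluates the objective at
  frequencies multiplied elementwise by independent N(1, sigma_p^2) noise,
  which keeps the Monte-Carlo frequency sample from co-adapting while
  leaving the covariance estimate unbiased; and
* early stopping — a held-out validation split is scored every
  ``eval_interval`` steps with *noise-free* frequencies, and optimisation
  halts once the validation MSE has failed to improve for more than
  ``patience`` consecutive evaluations. The returned model is the best
  validation checkpoint, not the last iterate.

ADAM is implemented here directly (standard moment estimates,
beta1=0.9, beta2=0.999, eps=1e-8).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .features import Standardizer
from .inference import GPFit, Hyperparameters, fit_gp, lml_value_and_grad, predict
from .spectral import FrequencyMatrix, FrequencyPairSet, SpectralSpec, sample_frequencies

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "TrainingState",
    "apply_gaussian_dropout",
    "training_step",
    "train",
    "initial_num_features",
    "select_num_features",
    "random_search",
]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class TrainingConfig:
    """Knobs of the optimisation loop.

    ``m`` is the number of frequencies (stationary) or frequency pairs
    (nonstationary); either way the feature map has 2m columns, so the two
    modes are compared at equal feature budget. ``dropout_sigma_p`` is the
    standard deviation of the multiplicative N(1, sigma_p^2) dropout noise
    (0 disables it; 0.05 is the default working value). The train /
    validation split fraction feeds early stopping only — outer test
    splits belong to the evaluation harness.

    ``learn_frequencies=False`` gives the vanilla random-feature baseline:
    frequencies stay fixed at their draw from ``init_spec`` and only the
    noise/scale variances are optimised, which is the classical stationary
    RFF-GP that frequency learning is compared against.
    """

    m: int = 32
    mode: str = "nonstationary"  # or "stationary"
    learning_rate: float = 0.01
    max_steps: int = 500
    eval_interval: int = 25
    patience: int = 10
    dropout_sigma_p: float = 0.05
    split_fraction: float = 0.7
    seed: int = 0
    init_spec: SpectralSpec | None = None
    learn_frequencies: bool = True
    standardize: bool = True
    sigma_n2_init: float | None = None  # default: 0.1 * var(y)
    sigma_f2_init: float | None = None  # default: var(y)

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.mode not in ("stationary", "nonstationary"):
            raise ValueError("mode must be 'stationary' or 'nonstationary'")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.dropout_sigma_p < 0:
            raise ValueError("dropout_sigma_p must be nonnegative")
        if self.patience < 0:
            raise ValueError("patience must be nonnegative")
        if self.patience >= self.max_steps / max(1, self.eval_interval):
            raise ValueError(
                "patience must be smaller than the number of evaluations "
                "(max_steps / eval_interval), otherwise early stopping can never trigger"
            )


@dataclass
class TrainingState:
    """Mutable optimiser state threaded through `training_step`."""

    params: dict  # omega1, omega2 (or None), log_sigma_n2, log_sigma_f2
    adam_m: dict
    adam_v: dict
    step: int
    rng: np.random.Generator
    loss_history: list = field(default_factory=list)

    def hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(
            sigma_n2=float(np.exp(self.params["log_sigma_n2"])),
            sigma_f2=float(np.exp(self.params["log_sigma_f2"])),
        )

    def frequencies(self):
        if self.params["omega2"] is None:
            return FrequencyMatrix(self.params["omega1"].copy(), provenance="learned")
        return FrequencyPairSet(
            FrequencyMatrix(self.params["omega1"].copy(), provenance="learned"),
            FrequencyMatrix(self.params["omega2"].copy(), provenance="learned"),
        )


@dataclass
class TrainedModel:
    """Best-validation checkpoint with its refit GP and training trace."""

    frequencies: FrequencyMatrix | FrequencyPairSet
    hp: Hyperparameters
    gpfit: GPFit
    trace: list  # dicts: step, train_lml, val_mse
    best_val_mse: float
    config: TrainingConfig
    mode: str


def apply_gaussian_dropout(pair, sigma_p: float, rng: np.random.Generator):
    """Multiply every frequency entry by an independent N(1, sigma_p^2) draw.

    Accepts a FrequencyPairSet or a single FrequencyMatrix; sigma_p = 0
    returns the input unchanged. Fresh noise is drawn on every call, and
    the multiplicative unit-mean form keeps the expected frequencies (and
    hence the covariance estimate) unbiased.
    """
    if sigma_p < 0:
        raise ValueError("sigma_p must be nonnegative")
    if sigma_p == 0:
        return pair
    if isinstance(pair, FrequencyPairSet):
        return FrequencyPairSet(
            apply_gaussian_dropout(pair.omega1, sigma_p, rng),
            apply_gaussian_dropout(pair.omega2, sigma_p, rng),
        )
    if isinstance(pair, FrequencyMatrix):
        eta = rng.normal(1.0, sigma_p, size=pair.entries.shape)
        return FrequencyMatrix(pair.entries * eta, provenance=pair.provenance)
    eta = rng.normal(1.0, sigma_p, size=np.shape(pair))
    return np.asarray(pair) * eta


def _adam_update(state: TrainingState, grads: dict, lr: float) -> None:
    t = state.step
    for key, g in grads.items():
        if g is None:
            continue
        loss_g = -np.asarray(g, float)  # minimise the negative log marginal likelihood
        state.adam_m[key] = _ADAM_B1 * state.adam_m[key] + (1 - _ADAM_B1) * loss_g
        state.adam_v[key] = _ADAM_B2 * state.adam_v[key] + (1 - _ADAM_B2) * loss_g**2
        mhat = state.adam_m[key] / (1 - _ADAM_B1**t)
        vhat = state.adam_v[key] / (1 - _ADAM_B2**t)
        state.params[key] = state.params[key] - lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)


def training_step(state: TrainingState, batch, config: TrainingConfig) -> TrainingState:
    """One ADAM update of {omega1, omega2, log sigma_n^2, log sigma_f^2}.

    The objective is the log marginal likelihood evaluated at
    dropout-noised frequencies; the noise multiplier enters the chain rule
    (d(w*eta)/dw = eta), so the clean parameters receive eta-weighted
    gradients. Noise is resampled every step.
    """
    Xs, y = batch
    sp = config.dropout_sigma_p
    eta1 = state.rng.normal(1.0, sp, size=state.params["omega1"].shape) if sp > 0 else 1.0
    noised1 = state.params["omega1"] * eta1
    if state.params["omega2"] is None:
        noised2 = eta2 = None
    else:
        eta2 = state.rng.normal(1.0, sp, size=state.params["omega2"].shape) if sp > 0 else 1.0
        noised2 = state.params["omega2"] * eta2

    lml, grad = lml_value_and_grad(
        Xs, y, noised1, noised2,
        state.params["log_sigma_n2"], state.params["log_sigma_f2"],
    )
    if not np.isfinite(lml) or any(
        g is not None and not np.all(np.isfinite(np.asarray(g))) for g in grad.values()
    ):
        raise FloatingPointError(
            f"non-finite objective or gradient at step {state.step + 1} "
            f"(lml={lml}); consider a smaller learning rate"
        )
    grad = dict(grad)
    if config.learn_frequencies:
        grad["omega1"] = grad["omega1"] * eta1
        if grad["omega2"] is not None:
            grad["omega2"] = grad["omega2"] * eta2
    else:
        # vanilla random-feature mode: frequencies stay at their sampled
        # values and only the hyperparameters are optimised
        grad["omega1"] = None
        grad["omega2"] = None

    state.step += 1
    _adam_update(state, grad, config.learning_rate)
    state.loss_history.append(-lml)
    return state


def _init_state(Xs: np.ndarray, y: np.ndarray, config: TrainingConfig, seed_seq) -> TrainingState:
    D = Xs.shape[1]
    spec = config.init_spec or SpectralSpec(family="gaussian", dim=D, lengthscales=1.0)
    s_init, s_drop = seed_seq.spawn(2)
    init_rng = np.random.default_rng(s_init)
    omega1 = sample_frequencies(spec, config.m, init_rng).entries
    omega2 = (
        sample_frequencies(spec, config.m, init_rng).entries
        if config.mode == "nonstationary"
        else None
    )
    var_y = max(float(np.var(y)), 1e-12)
    sn2 = config.sigma_n2_init if config.sigma_n2_init is not None else 0.1 * var_y
    sf2 = config.sigma_f2_init if config.sigma_f2_init is not None else var_y
    params = {
        "omega1": omega1,
        "omega2": omega2,
        "log_sigma_n2": float(np.log(sn2)),
        "log_sigma_f2": float(np.log(sf2)),
    }
    def zeros():
        return {k: (None if v is None else np.zeros_like(np.asarray(v, float))) for k, v in params.items()}

    return TrainingState(
        params=params,
        adam_m=zeros(),
        adam_v=zeros(),
        step=0,
        rng=np.random.default_rng(s_drop),
    )


def _as_xy(dataset):
    if hasattr(dataset, "X") and hasattr(dataset, "y"):
        return np.atleast_2d(np.asarray(dataset.X, float)), np.asarray(dataset.y, float).ravel()
    X, y = dataset
    return np.atleast_2d(np.asarray(X, float)), np.asarray(y, float).ravel()


def _val_mse(state: TrainingState, Xtr, ytr, Xval, yval, standardize: bool) -> float:
    fitted = fit_gp(Xtr, ytr, state.frequencies(), state.hyperparameters(), standardize=standardize)
    pred = predict(fitted, Xval)
    return float(np.mean((pred.mean - yval) ** 2))


def train(dataset, config: TrainingConfig) -> TrainedModel:
    """Full training loop: split, optimise, early-stop, refit best checkpoint.

    The data are split ``split_fraction`` / rest into an optimisation set
    and an early-stopping validation set. Gradients are full-batch on the
    optimisation set. Evaluation (every ``eval_interval`` steps, plus once
    at initialisation) fits a noise-free GP on the optimisation set and
    scores MSE on the validation set; the checkpoint with the lowest
    validation MSE is refit and returned.
    """
    X, y = _as_xy(dataset)
    if y.size < 10:
        raise ValueError("need at least 10 observations to train")
    ss = np.random.SeedSequence(config.seed)
    s_split, s_state = ss.spawn(2)
    split_seed = int(s_split.generate_state(1)[0] % (2**31))
    Xtr, Xval, ytr, yval = train_test_split(
        X, y, train_size=config.split_fraction, random_state=split_seed
    )
    if len(ytr) == 0 or len(yval) == 0:
        raise ValueError("degenerate train/validation split")

    std = Standardizer.fit(Xtr) if config.standardize else Standardizer.identity(X.shape[1])
    Xs = std.transform(Xtr)

    state = _init_state(Xs, ytr, config, s_state)
    best = {
        "params": copy.deepcopy(state.params),
        "val_mse": _val_mse(state, Xtr, ytr, Xval, yval, config.standardize),
        "step": 0,
    }
    trace = [{"step": 0, "train_lml": float("nan"), "val_mse": best["val_mse"]}]

    bad_evals = 0
    while state.step < config.max_steps:
        state = training_step(state, (Xs, ytr), config)
        if state.step % config.eval_interval == 0 or state.step == config.max_steps:
            val_mse = _val_mse(state, Xtr, ytr, Xval, yval, config.standardize)
            lml_clean, _ = lml_value_and_grad(
                Xs, ytr, state.params["omega1"], state.params["omega2"],
                state.params["log_sigma_n2"], state.params["log_sigma_f2"],
            )
            trace.append({"step": state.step, "train_lml": lml_clean, "val_mse": val_mse})
            if val_mse < best["val_mse"]:
                best = {"params": copy.deepcopy(state.params), "val_mse": val_mse, "step": state.step}
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals > config.patience:
                    break

    final = TrainingState(
        params=best["params"], adam_m={}, adam_v={}, step=best["step"], rng=state.rng
    )
    freqs = final.frequencies()
    hp = final.hyperparameters()
    gpfit = fit_gp(Xtr, ytr, freqs, hp, standardize=config.standardize)
    return TrainedModel(
        frequencies=freqs,
        hp=hp,
        gpfit=gpfit,
        trace=trace,
        best_val_mse=best["val_mse"],
        config=config,
        mode=config.mode,
    )


def initial_num_features(n: int, m_min: int = 2) -> int:
    """Feature-count starting point m0 = ceil(log(n) * sqrt(n)), natural log."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return max(m_min, math.ceil(math.log(n) * math.sqrt(n)))


def select_num_features(
    n: int, cv_curve_points: Sequence[tuple[int, float]] | None = None, rel_tol: float = 0.01
) -> int:
    """Pick the feature count where the CV error curve asymptotes.

    Start from m0 = ceil(log(n) sqrt(n)) and walk a doubling schedule of
    (m, cv_mse) points: once doubling m improves the CV MSE by less than
    ``rel_tol`` relatively, the smaller m already suffices and is
    returned. A flat (or absent) curve returns m0.
    """
    m0 = initial_num_features(n)
    if not cv_curve_points:
        return m0
    pts = sorted(cv_curve_points)
    for (m_prev, mse_prev), (_, mse_next) in zip(pts, pts[1:]):
        denom = abs(mse_prev) if mse_prev != 0 else 1.0
        if (mse_prev - mse_next) / denom < rel_tol:
            return m_prev
    return pts[-1][0]


def random_search(
    dataset,
    search_space: dict,
    n_samples: int,
    seed: int,
    base_config: TrainingConfig | None = None,
    n_runs: int = 3,
) -> TrainingConfig:
    """Log-uniform random search over {learning_rate, dropout_sigma_p}.

    Each sampled configuration is scored by the cross-validation harness
    (average test MSE over ``n_runs`` splits) and the argmin configuration
    is returned. The full protocol uses 500 samples; smaller budgets are
    the caller's choice.
    """
    from .evaluation import cross_validate  # local import to avoid a cycle

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not search_space:
        raise ValueError("search space is empty")
    for key in search_space:
        if key not in ("learning_rate", "dropout_sigma_p"):
            raise ValueError(f"unknown search dimension {key!r}")
    base = base_config or TrainingConfig()
    rng = np.random.default_rng(seed)
    best_cfg, best_mse = None, np.inf
    for i in range(n_samples):
        draw = {
            key: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for key, (lo, hi) in search_space.items()
        }
        cfg = replace(base, **draw)
        report = cross_validate(dataset, cfg, n_runs=n_runs, seed=seed + 1000 + i)
        if report.mse < best_mse:
            best_cfg, best_mse = cfg, report.mse
    return best_cfg
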