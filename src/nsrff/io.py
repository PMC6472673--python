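"""File formats: point CSVs, model files, run configuration.

Tabular data are header CSVs with numeric covariate columns (any names)
and an optional response column named ``y``. Models serialise to a single
JSON file holding the learned frequencies, hyperparameters and
standardisation constants — everything needed to rebuild the predictive
distribution; feature maps themselves are never serialised.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
import yaml

from .features import Standardizer
from .inference import GPFit, Hyperparameters
from .spectral import FrequencyMatrix, FrequencyPairSet

logger = logging.getLogger("nsrff")

__all__ = [
    "read_points",
    "write_predictions",
    "save_model",
    "load_model",
    "refit_from_model_file",
    "read_config",
]


def read_points(path):
    """Read (X, y-or-None) from a header CSV.

    All columns except one optionally named ``y`` are covariates, in file
    order. Rows containing any non-finite value are dropped with a logged
    warning carrying the count.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    finite = np.isfinite(df.to_numpy(float)).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, dropped)
        df = df.loc[finite]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: all rows non-finite")
    y = df.pop("y").to_numpy(float) if "y" in df.columns else None
    X = df.to_numpy(float)
    if X.shape[1] == 0:
        raise ValueError(f"{path}: no covariate columns")
    return X, y


def write_predictions(path, pred) -> None:
    pd.DataFrame({"mean": pred.mean, "sd": pred.sd}).to_csv(path, index=False)


def _freq_payload(freqs) -> dict:
    if isinstance(freqs, FrequencyPairSet):
        return {
            "mode": "nonstationary",
            "omega1": freqs.omega1.entries.tolist(),
            "omega2": freqs.omega2.entries.tolist(),
        }
    return {"mode": "stationary", "omega": freqs.entries.tolist()}


def save_model(path, model) -> None:
    """Persist a TrainedModel (or GPFit-carrying object) as JSON."""
    gpfit: GPFit = model.gpfit if hasattr(model, "gpfit") else model
    payload = {
        "format": "nsrff-model-v1",
        **_freq_payload(gpfit.frequencies),
        "hyperparameters": {"sigma_n2": gpfit.hp.sigma_n2, "sigma_f2": gpfit.hp.sigma_f2},
        "standardizer": {
            "mean": gpfit.standardizer.mean.tolist(),
            "std": gpfit.standardizer.std.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "nsrff-model-v1":
        raise ValueError(f"{path}: not a recognised model file")
    if payload["mode"] == "nonstationary":
        freqs = FrequencyPairSet(
            FrequencyMatrix(np.asarray(payload["omega1"], float), provenance="learned"),
            FrequencyMatrix(np.asarray(payload["omega2"], float), provenance="learned"),
        )
    else:
        freqs = FrequencyMatrix(np.asarray(payload["omega"], float), provenance="learned")
    hp = Hyperparameters(**payload["hyperparameters"])
    std = Standardizer(
        mean=np.asarray(payload["standardizer"]["mean"], float),
        std=np.asarray(payload["standardizer"]["std"], float),
    )
    return {"frequencies": freqs, "hp": hp, "standardizer": std, "mode": payload["mode"]}


def refit_from_model_file(path, X, y) -> GPFit:
    """Rebuild a GPFit from a saved model plus its training data."""
    m = load_model(path)
    from .features import nonstationary_features, stationary_features
    from .inference import fit as _fit

    Xs = m["standardizer"].transform(X)
    phi = (
        nonstationary_features(Xs, m["frequencies"])
        if m["mode"] == "nonstationary"
        else stationary_features(Xs, m["frequencies"])
    )
    return _fit(phi, y, m["hp"], frequencies=m["frequencies"], standardizer=m["standardizer"])


def read_config(path) -> dict:
    """Load a YAML (JSON-compatible) run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
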