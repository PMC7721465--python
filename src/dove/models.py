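"""Uniform fit/predict contract over the eight compared regression methods.

All eight methods — ordinary least squares, Bayesian ridge, lasso, AdaBoost,
k-nearest neighbors, a single decision tree, random forest, and extremely
randomized trees (the headline method) — run through one harness: identical
design matrices in, rates per 100,000 out.  Estimators are scikit-learn's;
hyperparameter defaults are the library's and are recorded in the run
manifest, since they are configuration rather than part of the contract.

Predictions are clipped at 0 (a death rate cannot be negative); the number
of clipped values is logged.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import BayesianRidge, Lasso, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["METHODS", "RegressorSpec", "FittedModel", "fit", "save_model", "load_model"]

#: Method name -> (estimator class, whether it accepts random_state)
_REGISTRY = {
    "OLS": (LinearRegression, False),
    "BAYESIAN_RIDGE": (BayesianRidge, False),
    "LASSO": (Lasso, True),
    "ADABOOST": (AdaBoostRegressor, True),
    "KNN": (KNeighborsRegressor, False),
    "DECISION_TREE": (DecisionTreeRegressor, True),
    "RANDOM_FOREST": (RandomForestRegressor, True),
    "EXTREMELY_RANDOM_FOREST": (ExtraTreesRegressor, True),
}

METHODS = tuple(_REGISTRY)


@dataclass(frozen=True)
class RegressorSpec:
    """One regression method plus its seed and hyperparameter overrides.

    With the seed fixed, fitting is reproducible bit-for-bit on identical
    input (randomized methods receive the seed as ``random_state``).
    """

    method: str
    seed: int = 0
    hyperparameters: tuple = field(default_factory=tuple)  # sorted (key, value) pairs

    def __post_init__(self) -> None:
        if self.method not in _REGISTRY:
            raise ValidationError(
                f"unknown method {self.method!r}; choose from {sorted(_REGISTRY)}"
            )
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    def make_estimator(self):
        cls, takes_seed = _REGISTRY[self.method]
        kwargs = dict(self.hyperparameters)
        if takes_seed:
            kwargs.setdefault("random_state", self.seed)
        return cls(**kwargs)


@dataclass
class FittedModel:
    """A fitted estimator bound to the exact feature names it was trained on."""

    spec: RegressorSpec
    feature_names: list[str]
    estimator: object

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Predict rates per 100,000; negative outputs are clipped to 0."""
        if list(X.columns) != self.feature_names:
            raise SchemaError(
                f"feature mismatch: model expects {self.feature_names}, got {list(X.columns)}"
            )
        if len(X) == 0:
            return pd.Series(dtype=float, index=X.index)
        if X.isna().any().any():
            raise ValidationError("NaN in prediction matrix")
        pred = np.asarray(self.estimator.predict(X.to_numpy(dtype=float)), dtype=float)
        if not np.all(np.isfinite(pred)):
            raise ValidationError("non-finite prediction")
        n_neg = int((pred < 0).sum())
        if n_neg:
            logger.info("clipped %d negative predicted rates to 0", n_neg)
            pred = np.clip(pred, 0.0, None)
        return pd.Series(pred, index=X.index)


def fit(spec: RegressorSpec, X: pd.DataFrame, y: pd.Series) -> FittedModel:
    """Fit ``spec`` on a design matrix and response (rates per 100,000)."""
    if len(X) < 2:
        raise ValidationError("need at least 2 training rows")
    if X.isna().any().any() or pd.Series(y).isna().any():
        raise ValidationError("NaN in training data")
    est = spec.make_estimator()
    est.fit(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return FittedModel(spec=spec, feature_names=list(X.columns), estimator=est)


_BUNDLE_VERSION = 1


def save_model(model: FittedModel, directory) -> None:
    """Persist a fitted model as a self-describing bundle (JSON + joblib)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": _BUNDLE_VERSION,
        "method": model.spec.method,
        "seed": model.spec.seed,
        "hyperparameters": dict(model.spec.hyperparameters),
        "feature_names": model.feature_names,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    joblib.dump(model.estimator, d / "estimator.joblib")


def load_model(directory) -> FittedModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise SchemaError(f"unsupported model bundle version {meta.get('bundle_version')}")
    spec = RegressorSpec(
        method=meta["method"], seed=meta["seed"], hyperparameters=tuple(sorted(meta["hyperparameters"].items()))
    )
    return FittedModel(
        spec=spec,
        feature_names=list(meta["feature_names"]),
        estimator=joblib.load(d / "estimator.joblib"),
    )
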