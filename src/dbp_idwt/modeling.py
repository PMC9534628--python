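"""Classifier training and prediction behind one uniform contract.

Four algorithm families are exposed under short tags:

* ``lixgb`` — light gradient boosting (LightGBM)
* ``xgb`` — extreme gradient boosting (XGBoost)
* ``ert`` — extremely randomized trees (scikit-learn ExtraTrees)
* ``adaboost`` — adaptive boosting (scikit-learn AdaBoost)

Default hyperparameters are the published configuration: learning rate
(eta) 0.1, 500 estimators, max depth 8, L1 (alpha) and L2 (lambda)
regularisation both 1; every other backend parameter is left at its
library default.  Parameter names are translated per backend by an
explicit mapping (eta->learning_rate, lambda->reg_lambda,
alpha->reg_alpha); parameters a backend has no counterpart for are
dropped, and the resolved mapping is recorded on the trained model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("lixgb", "xgb", "ert", "adaboost")


@dataclass
class ModelConfig:
    algorithm: str = "lixgb"
    eta: float = 0.1
    n_estimators: int = 500
    max_depth: int = 8
    alpha: float = 1.0
    lambda_: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be positive")
        for name in ("eta", "alpha", "lambda_"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels + sample identifiers."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match X rows")
        if not self.ids:
            self.ids = [f"sample_{i}" for i in range(self.X.shape[0])]
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match X rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], [self.ids[i] for i in idx])


@dataclass
class TrainedModel:
    algorithm: str
    estimator: Any
    feature_count: int
    seed: int
    config_hash: str
    param_mapping: dict[str, str] = field(default_factory=dict)


def _build_estimator(config: ModelConfig) -> tuple[Any, dict[str, str]]:
    common = dict(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=config.seed,
    )
    if config.algorithm == "lixgb":
        from lightgbm import LGBMClassifier

        mapping = {"eta": "learning_rate", "alpha": "reg_alpha", "lambda": "reg_lambda"}
        est = LGBMClassifier(
            learning_rate=config.eta,
            reg_alpha=config.alpha,
            reg_lambda=config.lambda_,
            n_jobs=1,
            verbose=-1,
            **common,
        )
    elif config.algorithm == "xgb":
        from xgboost import XGBClassifier

        mapping = {"eta": "learning_rate", "alpha": "reg_alpha", "lambda": "reg_lambda"}
        est = XGBClassifier(
            learning_rate=config.eta,
            reg_alpha=config.alpha,
            reg_lambda=config.lambda_,
            n_jobs=1,
            verbosity=0,
            **common,
        )
    elif config.algorithm == "ert":
        # no boosting rate or L1/L2 counterpart; dropped
        mapping = {"eta": "(dropped)", "alpha": "(dropped)", "lambda": "(dropped)"}
        est = ExtraTreesClassifier(n_jobs=1, **common)
    else:  # adaboost
        mapping = {
            "eta": "learning_rate",
            "alpha": "(dropped)",
            "lambda": "(dropped)",
            "max_depth": "(dropped)",
        }
        est = AdaBoostClassifier(
            n_estimators=config.n_estimators,
            learning_rate=config.eta,
            random_state=config.seed,
        )
    return est, mapping


def train(config: ModelConfig, dataset: LabeledDataset) -> TrainedModel:
    """Fit a classifier; deterministic under a fixed config seed.

    Raises
    ------
    ValueError
        On a single-class dataset, fewer than two samples per class,
        or NaN features (the message names the first offending sample).
    """
    classes, counts = np.unique(dataset.y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires samples from both classes")
    if counts.min() < 2:
        raise ValueError("training requires at least 2 samples per class")
    bad = np.where(~np.isfinite(dataset.X).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite features in sample {dataset.ids[bad[0]]!r}")
    est, mapping = _build_estimator(config)
    logger.info(
        "training %s (%d estimators, depth %d); parameter mapping: %s",
        config.algorithm,
        config.n_estimators,
        config.max_depth,
        mapping,
    )
    est.fit(dataset.X, dataset.y)
    return TrainedModel(
        algorithm=config.algorithm,
        estimator=est,
        feature_count=dataset.n_features,
        seed=config.seed,
        config_hash=config.config_hash(),
        param_mapping=mapping,
    )


def scores_to_labels(scores: np.ndarray) -> np.ndarray:
    """Decision rule: label 1 iff score >= 0.5 (ties are positive)."""
    return (np.asarray(scores) >= 0.5).astype(int)


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and positive-class scores for a feature matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.feature_count:
        raise ValueError(
            f"feature count mismatch: model expects {model.feature_count}, "
            f"got {features.shape[1]}"
        )
    import warnings

    with warnings.catch_warnings():
        # LightGBM registers synthetic feature names on ndarray fits,
        # which trips sklearn's name-consistency check spuriously
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        scores = model.estimator.predict_proba(features)[:, 1]
    return scores_to_labels(scores), scores
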