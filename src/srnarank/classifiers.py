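"""The five classifier families and the probabilistic ranking interface.

Families (scikit-learn estimators behind a uniform config/train/predict
surface):

* ``LR`` — logistic regression with class weights inversely proportional
  to class frequencies (the highly unbalanced datasets make unweighted
  fits collapse onto the majority class);
* ``MP`` — one hidden layer of 400 logistic units trained by plain SGD
  backpropagation at a constant learning rate of 0.9, L2 penalty 1e-4;
* ``RF`` — 400 trees, depth 20, Gini splits, 2 features considered per
  split, probability = mean of per-tree class frequencies;
* ``AB`` — AdaBoost over 100 depth-1 stumps;
* ``GB`` — stochastic gradient boosting, 50 trees of depth 15, minimum 5
  samples per leaf, 0.9 subsampling.

These hyperparameter defaults are the tuned settings for the sRNA
prioritization task (LOO-CV AUC maximization on the training data); they
can all be overridden per config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .context_features import FEATURE_COLUMNS
from .dataset_builder import LabeledDataset

FAMILIES = ("LR", "MP", "RF", "AB", "GB")

_DEFAULTS: dict[str, dict] = {
    "LR": {"class_weight": "balanced", "max_iter": 1000},
    "MP": {
        "hidden_units": 400,
        "activation": "logistic",
        "learning_rate_init": 0.9,
        "l2": 0.0001,
        "max_iter": 200,
    },
    "RF": {"n_trees": 400, "max_depth": 20, "max_features": 2, "criterion": "gini"},
    "AB": {"n_estimators": 100, "stump_depth": 1},
    "GB": {"n_estimators": 50, "max_depth": 15, "min_leaf": 5, "subsample": 0.9},
}


@dataclass(frozen=True)
class ClassifierConfig:
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        unknown = set(self.params) - set(_DEFAULTS[self.family])
        if unknown:
            raise ValueError(f"unknown {self.family} parameters: {sorted(unknown)}")

    def resolved(self) -> dict:
        p = dict(_DEFAULTS[self.family])
        p.update(self.params)
        return p


def default_config(family: str) -> ClassifierConfig:
    return ClassifierConfig(family)


@dataclass
class TrainedModel:
    config: ClassifierConfig
    estimator: object
    feature_schema: list[str]
    provenance: dict = field(default_factory=dict)


def _build_estimator(cfg: ClassifierConfig, seed: int | None):
    p = cfg.resolved()
    if cfg.family == "LR":
        return LogisticRegression(
            class_weight=p["class_weight"], max_iter=p["max_iter"], random_state=seed
        )
    if cfg.family == "MP":
        return MLPClassifier(
            hidden_layer_sizes=(p["hidden_units"],),
            activation=p["activation"],
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=p["learning_rate_init"],
            alpha=p["l2"],
            max_iter=p["max_iter"],
            random_state=seed,
        )
    if cfg.family == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"],
            max_depth=p["max_depth"],
            max_features=p["max_features"],
            criterion=p["criterion"],
            random_state=seed,
        )
    if cfg.family == "AB":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=p["stump_depth"]),
            n_estimators=p["n_estimators"],
            random_state=seed,
        )
    if cfg.family == "GB":
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            min_samples_leaf=p["min_leaf"],
            subsample=p["subsample"],
            random_state=seed,
        )
    raise AssertionError(cfg.family)


def _check_training_data(data: LabeledDataset) -> None:
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    X = data.X.to_numpy(dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        name = data.features["name"].iloc[row]
        raise ValueError(f"non-finite feature value in row {row} ({name!r})")


def train(cfg: ClassifierConfig, data: LabeledDataset, seed: int = 0) -> TrainedModel:
    """Fit one classifier family on a labelled feature table (seeded)."""
    _check_training_data(data)
    est = _build_estimator(cfg, seed)
    est.fit(data.X.to_numpy(dtype=float), data.y)
    return TrainedModel(
        config=cfg,
        estimator=est,
        feature_schema=list(FEATURE_COLUMNS),
        provenance={"seed": seed, "n_train": len(data)},
    )


def tune_loocv(grid: Sequence[ClassifierConfig], data: LabeledDataset, seed: int = 0) -> ClassifierConfig:
    """Pick the config maximizing leave-one-out cross-validated AUC.

    Each instance is scored by a model trained on all others; the pooled
    held-out scores give one AUC per config. Ties go to the first config
    in grid order.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    X = data.X.to_numpy(dtype=float)
    y = data.y
    best_cfg, best_auc = None, -np.inf
    for cfg in grid:
        scores = loocv_scores(cfg, data, seed=seed)
        auc = roc_auc_score(y, scores)
        if auc > best_auc:
            best_cfg, best_auc = cfg, auc
    return best_cfg


def loocv_scores(cfg: ClassifierConfig, data: LabeledDataset, seed: int = 0) -> np.ndarray:
    """Held-out probability for every instance (vector of length n)."""
    _check_training_data(data)
    X = data.X.to_numpy(dtype=float)
    y = data.y
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a LOO fold lost one class entirely")
        est = _build_estimator(cfg, seed)
        est.fit(X[mask], y[mask])
        scores[i] = est.predict_proba(X[i : i + 1])[0, 1]
    return scores


def _check_schema(model: TrainedModel, features: pd.DataFrame) -> None:
    missing = [c for c in model.feature_schema if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Probability of being a bona fide sRNA, one value per row in [0, 1]."""
    _check_schema(model, features)
    if len(features) == 0:
        return np.empty(0)
    X = features[model.feature_schema].to_numpy(dtype=float)
    return model.estimator.predict_proba(X)[:, 1]


def rank(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Candidates sorted by descending probability (stable; ties keep input order)."""
    probs = predict_proba(model, features)
    out = pd.DataFrame({"name": features["name"].to_numpy(), "probability": probs})
    order = np.argsort(-probs, kind="stable")
    out = out.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


MODEL_FORMAT = "srnarank-model"
MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format": MODEL_FORMAT,
            "version": MODEL_FORMAT_VERSION,
            "config": {"family": model.config.family, "params": model.config.params},
            "feature_schema": model.feature_schema,
            "estimator": model.estimator,
            "provenance": model.provenance,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
    return TrainedModel(
        config=ClassifierConfig(blob["config"]["family"], blob["config"]["params"]),
        estimator=blob["estimator"],
        feature_schema=blob["feature_schema"],
        provenance=blob.get("provenance", {}),
    )
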