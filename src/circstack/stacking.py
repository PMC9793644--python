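"""Two-layer stacking classifier and the evaluation metrics.

Layer one holds three tree-ensemble base learners — a random forest and
two gradient-boosted tree variants (XGBoost- and LightGBM-style). Each is
trained in a stratified 5-fold scheme: for every fold, a model fitted on
the other four folds predicts positive-class probabilities for the
held-out rows, so every training row receives exactly one out-of-fold
probability per base learner, produced by a model that never saw it.
Those three OOF probability columns train a logistic-regression
meta-learner against the original labels.

At prediction time the five retained fold-models of each base learner are
averaged into one meta-feature per learner, and the meta-learner maps the
three meta-features to the final probability (binary call at 0.5).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .selection import FeatureMatrix, InputError

logger = logging.getLogger(__name__)

EstimatorFactory = Callable[[int], object]  # seed -> unfitted classifier


def _rf_factory(seed: int):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(random_state=seed, n_jobs=1)


def _xgb_factory(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss")


def _lgbm_factory(seed: int):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)


DEFAULT_BASE_LEARNERS: tuple[tuple[str, EstimatorFactory], ...] = (
    ("rf", _rf_factory),
    ("xgboost", _xgb_factory),
    ("lightgbm", _lgbm_factory),
)


@dataclass(frozen=True)
class StackingConfig:
    base_learners: tuple[tuple[str, EstimatorFactory], ...] = DEFAULT_BASE_LEARNERS
    n_folds: int = 5
    threshold: float = 0.5
    meta_max_iter: int = 1000


@dataclass
class StackedModel:
    config: StackingConfig
    feature_names: list[str]
    base_names: list[str]
    fold_models: dict[str, list[object]]  # base name -> n_folds fitted models
    meta_model: LogisticRegression
    fold_assignment: np.ndarray  # per training row
    oof_meta_features: np.ndarray  # (n_train, n_base)
    seed: int


def fit_stacked(
    train: FeatureMatrix,
    config: StackingConfig | None = None,
    seed: int = 0,
) -> StackedModel:
    """Fit the two-layer stacking model on a labeled feature matrix."""
    config = config or StackingConfig()
    if train.labels is None:
        raise InputError("training matrix has no labels")
    y = np.asarray(train.labels)
    if len(np.unique(y)) < 2:
        raise InputError("training labels contain a single class")
    n = len(y)
    if n < 2 * config.n_folds:
        raise InputError(f"need >= {2 * config.n_folds} rows for {config.n_folds}-fold stacking")
    X = train.values

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_assignment = np.empty(n, dtype=int)
    for f, (_, va) in enumerate(folds):
        fold_assignment[va] = f

    n_base = len(config.base_learners)
    oof = np.empty((n, n_base))
    fold_models: dict[str, list[object]] = {}
    for b, (name, factory) in enumerate(config.base_learners):
        models = []
        for f, (tr, va) in enumerate(folds):
            est = factory(seed)
            est.fit(X[tr], y[tr])
            oof[va, b] = est.predict_proba(X[va])[:, 1]
            models.append(est)
        fold_models[name] = models

    meta = LogisticRegression(max_iter=config.meta_max_iter, random_state=seed)
    meta.fit(oof, y)
    return StackedModel(
        config=config,
        feature_names=list(train.feature_names),
        base_names=[name for name, _ in config.base_learners],
        fold_models=fold_models,
        meta_model=meta,
        fold_assignment=fold_assignment,
        oof_meta_features=oof,
        seed=seed,
    )


def base_meta_features(model: StackedModel, data: FeatureMatrix) -> np.ndarray:
    """Fold-averaged base-learner probabilities, one column per base learner."""
    if data.feature_names != model.feature_names:
        missing = set(model.feature_names) - set(data.feature_names)
        extra = set(data.feature_names) - set(model.feature_names)
        raise InputError(
            f"feature mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    X = data.values
    n_base = len(model.base_names)
    out = np.zeros((len(X), n_base))
    if len(X) == 0:
        return out
    for b, name in enumerate(model.base_names):
        probs = np.stack([m.predict_proba(X)[:, 1] for m in model.fold_models[name]])
        out[:, b] = probs.mean(axis=0)
    return out


def predict_stacked(
    model: StackedModel, data: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row positive-class probability and binary call at the threshold."""
    meta_in = base_meta_features(model, data)
    if len(meta_in) == 0:
        return np.empty(0), np.empty(0, dtype=int)
    probs = model.meta_model.predict_proba(meta_in)[:, 1]
    calls = (probs >= model.config.threshold).astype(int)
    return probs, calls


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_calls(cls, calls: np.ndarray, labels: np.ndarray) -> "ConfusionMatrix":
        calls = np.asarray(calls).astype(int)
        labels = np.asarray(labels).astype(int)
        if calls.shape != labels.shape:
            raise InputError("calls and labels must have equal length")
        if calls.size == 0:
            raise InputError("nothing to evaluate")
        return cls(
            tp=int(np.sum((calls == 1) & (labels == 1))),
            tn=int(np.sum((calls == 0) & (labels == 0))),
            fp=int(np.sum((calls == 1) & (labels == 0))),
            fn=int(np.sum((calls == 0) & (labels == 1))),
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    total = tp + tn + fp + fn
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return {
        "acc": _safe_div(tp + tn, total),
        "precision": _safe_div(tp, tp + fp),
        "recall": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "f1": _safe_div(2 * tp, 2 * tp + fp + fn),
        "mcc": float(mcc),
    }


def evaluate(
    calls: np.ndarray,
    labels: np.ndarray,
    probs: np.ndarray | None = None,
) -> dict[str, float]:
    """Standard binary metrics (ACC, precision, recall, Sp, F1, MCC)."""
    cm = ConfusionMatrix.from_calls(calls, labels)
    out = metrics_from_confusion(cm)
    out.update({"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn})
    return out


# ---------------------------------------------------------------------------
# persistence


def save_model(model: StackedModel, directory: str | Path) -> None:
    """Persist a fitted model: JSON metadata plus serialized estimators."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "feature_names": model.feature_names,
        "base_names": model.base_names,
        "n_folds": model.config.n_folds,
        "threshold": model.config.threshold,
        "seed": model.seed,
        "fold_assignment": model.fold_assignment.tolist(),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    # base-learner factories may be arbitrary callables; only the fitted
    # estimators are serialized, which is all inference needs
    joblib.dump(
        {
            "fold_models": model.fold_models,
            "meta_model": model.meta_model,
            "oof": model.oof_meta_features,
        },
        directory / "models.joblib",
    )


def load_model(directory: str | Path) -> StackedModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    blob = joblib.load(directory / "models.joblib")
    return StackedModel(
        config=StackingConfig(n_folds=meta["n_folds"], threshold=meta["threshold"]),
        feature_names=meta["feature_names"],
        base_names=meta["base_names"],
        fold_models=blob["fold_models"],
        meta_model=blob["meta_model"],
        fold_assignment=np.array(meta["fold_assignment"], dtype=int),
        oof_meta_features=blob["oof"],
        seed=meta["seed"],
    )
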