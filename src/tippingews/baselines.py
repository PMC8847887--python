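"""Classical ML baselines over EWS feature vectors.

Four standard learners — logistic regression, RBF-kernel SVM, random forest
and a one-hidden-layer MLP — classify series into C.T./S.T./N.T. from the
concatenated Kendall-tau trends of the generic indicators.  Margin- and
gradient-based learners get train-set z-scoring; the forest is scale-free
and is trained on raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["BaselineConfig", "train_baseline", "evaluate_baseline", "MODEL_KINDS"]

MODEL_KINDS = ("logistic_regression", "svm", "random_forest", "mlp")


@dataclass(frozen=True)
class BaselineConfig:
    """Which classical learner to fit, with optional hyperparameter overrides."""

    model_kind: str = "random_forest"
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")


def _make_estimator(config: BaselineConfig):
    hp = dict(config.hyperparameters)
    if config.model_kind == "logistic_regression":
        est = LogisticRegression(C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 2000), **hp)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.model_kind == "svm":
        est = SVC(
            C=hp.pop("C", 1.0),
            kernel=hp.pop("kernel", "rbf"),
            gamma=hp.pop("gamma", "scale"),
            probability=True,
            random_state=config.seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.model_kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100,)),
            early_stopping=hp.pop("early_stopping", True),
            max_iter=hp.pop("max_iter", 500),
            random_state=config.seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return RandomForestClassifier(
        n_estimators=dict(hp).pop("n_estimators", 500),
        random_state=config.seed,
        **{k: v for k, v in hp.items() if k != "n_estimators"},
    )


def train_baseline(features: np.ndarray, labels, config: BaselineConfig):
    """Fit a 3-class classifier exposing predict / predict_proba."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.size == 0 or X.ndim != 2:
        raise ValueError("features must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (apply the NaN policy upstream)")
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes")
    est = _make_estimator(config)
    est.fit(X, y)
    return est


def evaluate_baseline(classifier, features: np.ndarray, labels) -> dict:
    """Accuracy, macro one-vs-rest AUC, per-class TPR/precision/F-score and
    the (count) confusion matrix of a fitted classifier."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes = np.asarray(classifier.classes_)
    unknown = set(np.unique(y)) - set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} unseen during training")
    pred = classifier.predict(X)
    proba = classifier.predict_proba(X)
    acc = float(np.mean(pred == y))
    conf = np.zeros((classes.size, classes.size), dtype=int)
    cindex = {c: i for i, c in enumerate(classes)}
    for yt, yp in zip(y, pred):
        conf[cindex[yt], cindex[yp]] += 1
    per_class = {}
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tpr = tp / (tp + fn) if tp + fn else float("nan")
        prec = tp / (tp + fp) if tp + fp else float("nan")
        f1 = (
            2 * prec * tpr / (prec + tpr)
            if np.isfinite(prec) and np.isfinite(tpr) and (prec + tpr) > 0
            else float("nan")
        )
        per_class[str(c)] = {"tpr": float(tpr), "precision": float(prec), "f_score": float(f1)}
    try:
        auc = float(roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=classes))
    except ValueError:
        auc = float("nan")  # a class absent from y
    return {
        "accuracy": acc,
        "auc_macro_ovr": auc,
        "per_class": per_class,
        "confusion": conf,
        "classes": [str(c) for c in classes],
    }
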