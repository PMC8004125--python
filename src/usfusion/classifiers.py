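"""Conventional classifier heads for the texture-feature baseline.

Thin, uniformly-interfaced wrappers: each baseline takes a selected
feature matrix and emits normalized (HCC, PAR) probabilities consumable
by the ROC machinery.  The heads themselves are standard library
estimators — the bespoke computation of this package lives in the
texture, selection and fusion modules.

Configured per the study protocol: polynomial-kernel SVM (degree 1, 3
or 5), an MLP with up to three hidden layers whose width is the mean of
the class count and the feature count (momentum 0.8, learning rate 0.2,
500 epochs), AdaBoost over decision trees with 100 iterations, and a
100-tree random forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import HCC
from .evaluation import confusion_from_scores, confusion_metrics, roc_auc

METHODS = ("svm_poly", "mlp", "adaboost_trees", "random_forest")


@dataclass
class BaselineConfig:
    method: str = "random_forest"
    svm_degree: int = 3
    mlp_hidden_layers: int = 1
    mlp_momentum: float = 0.8
    mlp_learning_rate: float = 0.2
    mlp_epochs: int = 500
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.svm_degree not in (1, 3, 5):
            raise ValueError("svm degree must be 1, 3 or 5")
        if not 1 <= self.mlp_hidden_layers <= 3:
            raise ValueError("mlp supports 1-3 hidden layers")
        if self.n_iterations < 1 or self.mlp_epochs < 1:
            raise ValueError("iteration counts must be positive")


def _build(config: BaselineConfig, n_features: int):
    from sklearn.ensemble import (AdaBoostClassifier,
                                  RandomForestClassifier)
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if config.method == "svm_poly":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="poly", degree=config.svm_degree, probability=True,
                random_state=config.seed))
    if config.method == "mlp":
        # node count: mean of the class count (2) and the feature count
        nodes = max(2, int(round((2 + n_features) / 2)))
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(nodes,) * config.mlp_hidden_layers,
                          solver="sgd", momentum=config.mlp_momentum,
                          learning_rate_init=config.mlp_learning_rate,
                          max_iter=config.mlp_epochs,
                          random_state=config.seed))
    if config.method == "adaboost_trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3,
                                             random_state=config.seed),
            n_estimators=config.n_iterations, random_state=config.seed)
    return RandomForestClassifier(n_estimators=config.n_iterations,
                                  random_state=config.seed)


def fit_predict_baseline(X_train: np.ndarray, y_train, X_test: np.ndarray,
                         y_test=None, config: BaselineConfig | None = None):
    """Fit one baseline and score the test set.

    Returns ``(hcc_scores, metrics)``; metrics is None when ``y_test``
    is not given.  Deterministic given ``config.seed``.
    """
    config = config or BaselineConfig()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    model = _build(config, np.asarray(X_train).shape[1])
    model.fit(np.asarray(X_train, dtype=float), y_train)
    proba = model.predict_proba(np.asarray(X_test, dtype=float))
    hcc_col = int(np.flatnonzero(model.classes_ == HCC)[0])
    scores = proba[:, hcc_col]
    metrics = None
    if y_test is not None:
        acc, sens, spec = confusion_metrics(
            confusion_from_scores(scores, y_test))
        _, auc = roc_auc(scores, y_test)
        metrics = {"accuracy": acc, "sensitivity": sens,
                   "specificity": spec, "auc": auc}
    return scores, metrics
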