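"""Classic ML comparators on the 98-dimensional feature vectors.

Thin wrappers over scikit-learn: logistic regression, decision tree, SVM and
random forest, each with an optional cost-sensitive variant that weights the
positive class (same spirit as the GCN's w_c).  Baselines consume exactly
the same cohort splits as the graph model so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

BASELINE_NAMES = ("LR", "DT", "SVM", "RF")


@dataclass
class BaselineSpec:
    """Which comparator to fit, and whether to weight the positive class."""

    name: str
    cost_sensitive: bool = False
    positive_weight: float | None = None  # None -> inverse prevalence
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; expected one of {BASELINE_NAMES}"
            )


def _class_weight(spec: BaselineSpec, y_train: np.ndarray):
    if not spec.cost_sensitive:
        return None
    if spec.positive_weight is not None:
        return {0: 1.0, 1: float(spec.positive_weight)}
    return "balanced"


def fit_baseline(spec: BaselineSpec, Z_train: np.ndarray, y_train: np.ndarray):
    """Fit the requested classifier; deterministic for a fixed seed."""
    spec.validate()
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    cw = _class_weight(spec, y_train)
    hp = dict(spec.hyperparameters)
    if spec.name == "LR":
        model = LogisticRegression(
            max_iter=1000, class_weight=cw, random_state=spec.seed, **hp
        )
    elif spec.name == "DT":
        model = DecisionTreeClassifier(class_weight=cw, random_state=spec.seed, **hp)
    elif spec.name == "SVM":
        model = SVC(class_weight=cw, random_state=spec.seed, **hp)
    else:  # RF
        model = RandomForestClassifier(
            class_weight=cw, random_state=spec.seed, **hp
        )
    model.fit(np.asarray(Z_train, dtype=float), y_train)
    return model


def predict_baseline(model, Z_test: np.ndarray) -> np.ndarray:
    """Hard 0/1 labels from a fitted comparator."""
    return np.asarray(model.predict(np.asarray(Z_test, dtype=float)), dtype=np.int8)
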