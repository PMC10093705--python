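"""Bench of conventional classifiers for comparison with the FMMN.

The seven names mirror a classic machine-learning workbench lineup
(BayesNet, Naive Bayes, random forest, random tree, decision table,
PART rule learner, simple logistic).  Exact replication of those
implementations is a non-goal; each name maps to a documented
scikit-learn analogue so the comparison structure (identical splits and
metrics) is preserved:

========== =================================================== ========
name        analogue                                            flagged
========== =================================================== ========
bayes_net       LinearDiscriminantAnalysis (correlated-feature
                Gaussian Bayes classifier)                        yes
naive_bayes     GaussianNB                                        no
random_forest   RandomForestClassifier                            no
random_tree     DecisionTreeClassifier(splitter="random",
                max_features="sqrt")                              yes
decision_table  DecisionTreeClassifier(max_depth=4)               yes
rule_part       DecisionTreeClassifier (one rule per leaf)        yes
simple_logistic LogisticRegression                                yes
========== =================================================== ========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, ShapeError
from .features import FeatureMatrix

__all__ = ["BaselineSpec", "BASELINE_NAMES", "fit_predict", "is_analogue"]

BASELINE_NAMES = (
    "bayes_net",
    "naive_bayes",
    "random_forest",
    "random_tree",
    "decision_table",
    "rule_part",
    "simple_logistic",
)

# names whose sklearn stand-in differs algorithmically from the original tool
_ANALOGUE = {
    "bayes_net",
    "random_tree",
    "decision_table",
    "rule_part",
    "simple_logistic",
}


@dataclass(frozen=True)
class BaselineSpec:
    """One bench entry: classifier name, overrides and seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ConfigError(
                f"unknown baseline '{self.name}'; choose from {BASELINE_NAMES}"
            )


def is_analogue(name: str) -> bool:
    """True when the sklearn stand-in is not the original tool's algorithm."""
    return name in _ANALOGUE


def _build(spec: BaselineSpec):
    p = dict(spec.params)
    if spec.name == "bayes_net":
        return LinearDiscriminantAnalysis(**p)
    if spec.name == "naive_bayes":
        return GaussianNB(**p)
    if spec.name == "random_forest":
        p.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.name == "random_tree":
        p.setdefault("splitter", "random")
        p.setdefault("max_features", "sqrt")
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.name == "decision_table":
        p.setdefault("max_depth", 4)
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.name == "rule_part":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.name == "simple_logistic":
        p.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **p)
    raise ConfigError(f"unknown baseline '{spec.name}'")  # pragma: no cover


def _values(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def fit_predict(
    spec: BaselineSpec, train_features, train_labels, test_features
) -> np.ndarray:
    """Train the named baseline and predict labels for the test rows.

    Deterministic for a fixed ``spec.seed``; one predicted label per
    test row, in test-row order.
    """
    xtr = _values(train_features)
    xte = _values(test_features)
    ytr = np.asarray(train_labels)
    if xtr.shape[0] != ytr.shape[0]:
        raise ShapeError(f"{xtr.shape[0]} training rows, {ytr.shape[0]} labels")
    if xtr.shape[1] != xte.shape[1]:
        raise ShapeError(
            f"train has {xtr.shape[1]} features, test has {xte.shape[1]}"
        )
    if np.unique(ytr).size == 1:
        # degenerate single-class training set: constant prediction
        return np.full(xte.shape[0], ytr[0])
    clf = _build(spec)
    clf.fit(xtr, ytr)
    return np.asarray(clf.predict(xte))
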