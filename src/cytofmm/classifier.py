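"""Single-pass online training and prediction for the fuzzy min-max net.

The network has three layers: input nodes FA (one per feature), hyperbox
nodes FB (one per learned hyperbox, computing the fuzzy membership of
the input) and class nodes FC.  A binary assignment matrix U routes each
hyperbox to its one class; a class node's activation is the maximum
membership over its hyperboxes, and prediction is winner-take-all over
class activations.

Training presents each sample once, in row order:

1. Among hyperboxes of the sample's class, in descending membership
   order, the first one passing the expansion test (summed edge lengths
   of the enclosing box <= n * theta) absorbs the pattern.
2. If none qualifies, a new point hyperbox (min = max = pattern) is
   created for that class.
3. After an expansion, the grown box is tested for overlap against every
   hyperbox of a *different* class and any positive-volume overlap is
   contracted away along the single least-overlapping dimension.

Small theta yields many small boxes (theta = 0: one per distinct
pattern); theta = 1 yields one box per class.  Same-class overlap is
left alone: it cannot change a winner-take-all decision routed by U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, NotTrainedError, ShapeError
from .features import FeatureMatrix
from .hyperbox import Hyperbox, can_expand, contract, expand, membership, overlap_test

__all__ = ["FMMNModel", "train", "predict", "resubstitution_accuracy"]


@dataclass
class FMMNModel:
    """A trained fuzzy min-max network.

    Attributes
    ----------
    hyperboxes
        Ordered hyperbox layer FB.
    theta
        Expansion parameter in [0, 1]: cap on summed edge lengths / n.
    gamma
        Membership sensitivity (decay slope outside a box); gamma > 0.
    class_ids
        Distinct class identifiers in order of first appearance during
        training (layer FC); this order breaks prediction ties.
    """

    hyperboxes: list[Hyperbox] = field(default_factory=list)
    theta: float = 0.3
    gamma: float = 1.0
    class_ids: list = field(default_factory=list)

    @property
    def n_hyperboxes(self) -> int:
        return len(self.hyperboxes)

    @property
    def assignment(self) -> np.ndarray:
        """Binary U matrix (hyperbox x class): u_jk = 1 iff box j votes for class k."""
        u = np.zeros((len(self.hyperboxes), len(self.class_ids)), dtype=int)
        for j, box in enumerate(self.hyperboxes):
            u[j, box.class_id] = 1
        return u

    def class_memberships(self, pattern) -> np.ndarray:
        """Per-class activation: max membership over each class's boxes."""
        scores = np.zeros(len(self.class_ids))
        for box in self.hyperboxes:
            m = membership(box, pattern, self.gamma)
            if m > scores[box.class_id]:
                scores[box.class_id] = m
        return scores


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        if not features.normalized:
            raise InvalidInputError(
                "FMMN requires normalized features (unit hypercube); "
                "run fit_normalizer/apply_normalizer first"
            )
        return features.values
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ShapeError("features must be a 2-D array")
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        raise InvalidInputError("features must lie in [0, 1] for the FMMN")
    return x


def train(features, labels, theta: float = 0.3, gamma: float = 1.0) -> FMMNModel:
    """Fit a fuzzy min-max network in one pass over the rows.

    Parameters
    ----------
    features
        Normalized ``FeatureMatrix`` or array in [0,1]^(m x n); samples
        are presented in row order (shuffle beforehand if desired).
    labels
        One class identifier per row; any hashable values.
    theta
        Expansion parameter in [0, 1].
    gamma
        Membership sensitivity, > 0.
    """
    x = _as_array(features)
    y = np.asarray(labels)
    if x.shape[0] == 0:
        raise InvalidInputError("empty training set")
    if y.shape[0] != x.shape[0]:
        raise ShapeError(f"{x.shape[0]} rows but {y.shape[0]} labels")
    if not 0.0 <= theta <= 1.0:
        raise InvalidInputError(f"theta must be in [0, 1], got {theta}")
    if gamma <= 0:
        raise InvalidInputError(f"gamma must be positive, got {gamma}")

    model = FMMNModel(theta=theta, gamma=gamma)
    class_index: dict = {}

    for pattern, label in zip(x, y):
        key = label.item() if hasattr(label, "item") else label
        if key not in class_index:
            class_index[key] = len(model.class_ids)
            model.class_ids.append(key)
        cid = class_index[key]

        # expansion: best same-class candidate by membership that passes Eq. 5
        candidates = [
            (j, box)
            for j, box in enumerate(model.hyperboxes)
            if box.class_id == cid
        ]
        candidates.sort(
            key=lambda jb: (-membership(jb[1], pattern, gamma), jb[0])
        )
        expanded_at = None
        for j, box in candidates:
            if can_expand(box, pattern, theta):
                model.hyperboxes[j] = expand(box, pattern)
                expanded_at = j
                break
        if expanded_at is None:
            model.hyperboxes.append(Hyperbox.point(pattern, cid))
            continue

        # overlap test + contraction against every other-class box
        for j, other in enumerate(model.hyperboxes):
            if other.class_id == cid:
                continue
            grown = model.hyperboxes[expanded_at]
            result = overlap_test(grown, other)
            if result.overlapping:
                new_g, new_o = contract(grown, other, result)
                model.hyperboxes[expanded_at] = new_g
                model.hyperboxes[j] = new_o

    return model


def predict(model: FMMNModel, features) -> np.ndarray:
    """Winner-take-all class prediction for each row.

    A class's score is the maximum membership over its hyperboxes; ties
    go to the class appearing first in ``model.class_ids``.
    """
    if not model.hyperboxes:
        raise NotTrainedError("model has no hyperboxes; train it first")
    x = _as_array(features)
    if x.shape[1] != model.hyperboxes[0].n_dims:
        raise ShapeError(
            f"features have {x.shape[1]} dims, model expects "
            f"{model.hyperboxes[0].n_dims}"
        )
    out = []
    for pattern in x:
        scores = model.class_memberships(pattern)
        out.append(model.class_ids[int(np.argmax(scores))])
    return np.asarray(out)


def resubstitution_accuracy(model: FMMNModel, features, labels) -> float:
    """Fraction of training samples the trained model labels correctly.

    A diagnostic of fit, not a generalization estimate.  At theta = 0
    with conflict-free labels it is exactly 1.0: every pattern sits in
    its own point hyperbox with membership 1.
    """
    y = np.asarray(labels)
    pred = predict(model, features)
    return float(np.mean(pred == y))
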