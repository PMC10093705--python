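"""Feature matrices and min-max normalization.

Min-max normalization rescales each feature column affinely so that the
training minimum maps to 0 and the training maximum to 1:

    x_new = (x - x_min) / (x_max - x_min)

The fuzzy min-max classifier operates on the unit hypercube I^n, so
normalization is a hard prerequisite for it, not a convenience.  Test
data is transformed with the *training* min/max and clipped to [0, 1];
a zero-range (constant) column maps to 0 with a warning, since such a
feature carries no class information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ShapeError

__all__ = [
    "FeatureMatrix",
    "NormalizationState",
    "fit_normalizer",
    "apply_normalizer",
    "load_feature_csv",
    "save_feature_csv",
    "load_normalization_state",
    "save_normalization_state",
]


@dataclass
class FeatureMatrix:
    """A samples x features real matrix with a normalization flag.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_features)``; finite, no missing
        entries.
    feature_names
        One identifier per column; generated as ``f0, f1, ...`` when
        omitted.
    normalized
        True when every entry is known to lie in [0, 1].
    """

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(
                f"feature matrix must be 2-D, got {self.values.ndim}-D"
            )
        if not np.isfinite(self.values).all():
            raise InvalidInputError("feature matrix contains NaN or inf")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ShapeError(
                f"{len(self.feature_names)} feature names for "
                f"{self.values.shape[1]} columns"
            )
        if self.normalized and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < 0.0 or hi > 1.0:
                raise InvalidInputError(
                    f"matrix flagged normalized but values span [{lo}, {hi}]"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizationState:
    """Per-column min and max learned from a training matrix."""

    per_feature_min: np.ndarray
    per_feature_max: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_feature_min = np.asarray(self.per_feature_min, dtype=float)
        self.per_feature_max = np.asarray(self.per_feature_max, dtype=float)
        if self.per_feature_min.shape != self.per_feature_max.shape:
            raise ShapeError("min and max vectors differ in length")
        if np.any(self.per_feature_min > self.per_feature_max):
            raise InvalidInputError("per-feature min exceeds max")

    @property
    def n_features(self) -> int:
        return self.per_feature_min.shape[0]


def fit_normalizer(features: FeatureMatrix) -> NormalizationState:
    """Learn columnwise min and max from a training feature matrix."""
    if features.n_samples < 1:
        raise InvalidInputError("cannot fit a normalizer on an empty matrix")
    return NormalizationState(
        per_feature_min=features.values.min(axis=0),
        per_feature_max=features.values.max(axis=0),
        feature_names=list(features.feature_names),
    )


def apply_normalizer(
    features: FeatureMatrix, state: NormalizationState
) -> FeatureMatrix:
    """Rescale each column to [0, 1] using a fitted state.

    Entries outside the fitted range (unseen test data) are clipped to
    [0, 1].  Zero-range columns map to 0 and trigger a ``UserWarning``.
    """
    if features.n_features != state.n_features:
        raise ShapeError(
            f"matrix has {features.n_features} features, "
            f"state was fitted on {state.n_features}"
        )
    span = state.per_feature_max - state.per_feature_min
    degenerate = span == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature(s) mapped to 0 "
            "(zero range under min-max normalization)",
            stacklevel=2,
        )
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (features.values - state.per_feature_min) / safe_span
    scaled[:, degenerate] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return FeatureMatrix(
        values=scaled,
        feature_names=list(features.feature_names),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# serialization

def save_feature_csv(
    path: str | Path, features: FeatureMatrix, labels
) -> None:
    """Write features plus a trailing ``label`` column as headered CSV."""
    df = pd.DataFrame(features.values, columns=features.feature_names)
    df["label"] = list(labels)
    df.to_csv(path, index=False)


def load_feature_csv(path: str | Path) -> tuple[FeatureMatrix, np.ndarray]:
    """Read a headered CSV with a trailing ``label`` column."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"no 'label' column in {path}")
    labels = df.pop("label").to_numpy()
    fm = FeatureMatrix(
        values=df.to_numpy(dtype=float), feature_names=list(df.columns)
    )
    return fm, labels


def save_normalization_state(path: str | Path, state: NormalizationState) -> None:
    doc = {
        "per_feature_min": state.per_feature_min.tolist(),
        "per_feature_max": state.per_feature_max.tolist(),
        "feature_names": state.feature_names,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_normalization_state(path: str | Path) -> NormalizationState:
    doc = json.loads(Path(path).read_text())
    return NormalizationState(
        per_feature_min=np.asarray(doc["per_feature_min"], dtype=float),
        per_feature_max=np.asarray(doc["per_feature_max"], dtype=float),
        feature_names=list(doc.get("feature_names", [])),
    )
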