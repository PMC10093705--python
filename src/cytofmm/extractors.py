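"""Pluggable image feature-extraction adapters.

Two families of extractor are exposed behind one interface:

* Pretrained-backbone adapters (``alexnet_fc7``, ``googlenet_loss3``,
  ``resnet18_pool5``, ``resnet50_fc1000``) read activations from a named
  layer of an ImageNet-pretrained network with the backbone frozen.
  Their declared output dimensionalities are 4096, 1000, 512 and 1000
  respectively.  They require torch/torchvision plus locally available
  weights; without that runtime they raise a clear error but their specs
  (names and dimensionalities) remain usable for planning and I/O.

* The ``toy`` extractor is a deterministic, download-free embedding:
  images are resized to 32 x 32 grayscale, convolved with a fixed 3 x 3
  edge/blob filter bank, average-pooled over a coarse grid, and
  concatenated with an intensity histogram; the vector is tiled or
  truncated to the requested ``output_dim``.  It exists so the whole
  pipeline (extract -> normalize -> train -> evaluate) runs end-to-end
  with no network access, bitwise reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve

from .errors import ConfigError, ExtractionError, InvalidInputError
from .features import FeatureMatrix

__all__ = ["ExtractorSpec", "get_extractor_spec", "extract_features", "BACKBONE_DIMS"]

# layer dimensionalities of the four supported pretrained backbones
BACKBONE_DIMS = {
    "alexnet_fc7": 4096,
    "googlenet_loss3": 1000,
    "resnet18_pool5": 512,
    "resnet50_fc1000": 1000,
}


@dataclass(frozen=True)
class ExtractorSpec:
    """Identity and output contract of a feature extractor."""

    name: str
    output_dim: int
    requires_weights: bool

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ConfigError(f"output_dim must be positive, got {self.output_dim}")
        if self.name in BACKBONE_DIMS and self.output_dim != BACKBONE_DIMS[self.name]:
            raise ConfigError(
                f"{self.name} emits {BACKBONE_DIMS[self.name]} features, "
                f"not {self.output_dim}"
            )


def get_extractor_spec(name: str, output_dim: int | None = None) -> ExtractorSpec:
    """Resolve an extractor name to its spec.

    ``output_dim`` is honored only for the ``toy`` extractor (default
    24); backbone dims are fixed by their architecture.
    """
    if name in BACKBONE_DIMS:
        return ExtractorSpec(name, BACKBONE_DIMS[name], requires_weights=True)
    if name == "toy":
        return ExtractorSpec("toy", output_dim or 24, requires_weights=False)
    raise ConfigError(
        f"unknown extractor '{name}'; choose from "
        f"{sorted(BACKBONE_DIMS) + ['toy']}"
    )


# ---------------------------------------------------------------------------
# toy extractor

# fixed 3x3 filter bank: identity-ish blob, horizontal/vertical/diagonal
# edges, Laplacian, corner detector
_FILTERS = np.array(
    [
        [[1, 1, 1], [1, 1, 1], [1, 1, 1]],          # blob / local mean
        [[-1, -1, -1], [0, 0, 0], [1, 1, 1]],       # horizontal edge
        [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]],       # vertical edge
        [[-1, -1, 0], [-1, 0, 1], [0, 1, 1]],       # diagonal edge
        [[0, 1, 0], [1, -4, 1], [0, 1, 0]],         # Laplacian
        [[1, -1, 0], [-1, 1, 0], [0, 0, 0]],        # corner
    ],
    dtype=float,
)
_TOY_SIZE = 32
_POOL = 4          # pool each response map to a 4x4 grid
_HIST_BINS = 8


def _toy_vector(img: Image.Image) -> np.ndarray:
    """Deterministic base embedding (6 filters x 16 pools + 8 hist bins = 104)."""
    gray = np.asarray(
        img.convert("L").resize((_TOY_SIZE, _TOY_SIZE), Image.BILINEAR),
        dtype=float,
    ) / 255.0
    parts = []
    step = _TOY_SIZE // _POOL
    for filt in _FILTERS:
        resp = convolve(gray, filt, mode="nearest")
        pooled = resp.reshape(_POOL, step, _POOL, step).mean(axis=(1, 3))
        parts.append(pooled.ravel())
    hist, _ = np.histogram(gray, bins=_HIST_BINS, range=(0.0, 1.0))
    parts.append(hist / gray.size)
    return np.concatenate(parts)


def _toy_features(img: Image.Image, output_dim: int) -> np.ndarray:
    base = _toy_vector(img)
    if output_dim <= base.size:
        return base[:output_dim]
    reps = -(-output_dim // base.size)
    return np.tile(base, reps)[:output_dim]


# ---------------------------------------------------------------------------
# backbone adapter contract

def _backbone_features(paths: list[Path], spec: ExtractorSpec) -> np.ndarray:
    """Frozen-backbone activation extraction at the spec's named layer."""
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ExtractionError(
            f"extractor '{spec.name}' needs the optional torch/torchvision "
            "runtime with locally available pretrained weights; install the "
            "'torch' extra or use the 'toy' extractor"
        ) from exc
    raise ExtractionError(
        f"backbone adapter '{spec.name}' has no weight bundle configured"
    )  # pragma: no cover - exercised only with the optional runtime


def extract_features(
    image_manifest, spec: ExtractorSpec
) -> tuple[FeatureMatrix, np.ndarray]:
    """Embed every image of a manifest into a feature matrix.

    Parameters
    ----------
    image_manifest
        A ``DatasetManifest`` or any iterable of ``(path, label)`` pairs;
        row order of the output equals manifest order.
    spec
        Which extractor to run; column count of the result equals
        ``spec.output_dim``.
    """
    entries = list(getattr(image_manifest, "entries", image_manifest))
    if not entries:
        raise InvalidInputError("empty image manifest")

    if spec.name in BACKBONE_DIMS:
        values = _backbone_features([Path(p) for p, _ in entries], spec)
    elif spec.name == "toy":
        rows = []
        for path, _ in entries:
            try:
                with Image.open(path) as img:
                    rows.append(_toy_features(img, spec.output_dim))
            except (OSError, ValueError) as exc:
                raise ExtractionError(f"unreadable image ({exc})", str(path)) from exc
        values = np.vstack(rows)
    else:
        raise ConfigError(f"unknown extractor '{spec.name}'")

    labels = np.asarray([label for _, label in entries])
    names = [f"{spec.name}_{i}" for i in range(spec.output_dim)]
    return FeatureMatrix(values=values, feature_names=names), labels
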