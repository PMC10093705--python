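"""Download-free fixtures: unit-cube blobs, toy cell images, manifests.

Three generators stand in for the data a real screening experiment
needs:

* ``generate_blobs`` draws isotropic Gaussian clusters inside the unit
  hypercube, emulating normalized deep-feature vectors with
  controllable class overlap (center spacing vs. spread).

* ``generate_toy_images`` renders tiny single-cell crops: an elliptical
  nucleus on a cytoplasm disc.  The "normal" class has a small round
  nucleus and large cytoplasm; the "abnormal" class an enlarged,
  irregular nucleus with a higher nucleus-to-cytoplasm ratio — the
  morphological cue cytoscreeners use.  Rendering is deterministic per
  seed, so fixtures are byte-identical across runs.

* ``build_manifest`` walks a class-labeled directory tree
  (``root/<class_name>/*.png`` etc.) and applies a raw-to-binary label
  map.  Built-in maps cover the Herlev seven-category and Sipakmed
  five-category layouts; the Sipakmed "metaplastic" category (benign)
  defaults to normal and is configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .errors import ConfigError, InvalidInputError
from .features import FeatureMatrix

__all__ = [
    "BlobSpec",
    "DatasetManifest",
    "generate_blobs",
    "generate_toy_images",
    "build_manifest",
    "HERLEV_BINARY_MAP",
    "SIPAKMED_BINARY_MAP",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

# seven Herlev cell categories -> screening binary classes
HERLEV_BINARY_MAP = {
    "normal_squamous": "normal",
    "intermediate_squamous": "normal",
    "columnar": "normal",
    "mild_dysplasia": "abnormal",
    "moderate_dysplasia": "abnormal",
    "severe_dysplasia": "abnormal",
    "carcinoma_in_situ": "abnormal",
}

# five Sipakmed categories; metaplastic is benign -> normal by default
SIPAKMED_BINARY_MAP = {
    "superficial_intermediate": "normal",
    "superficial": "normal",
    "parabasal": "normal",
    "koilocytotic": "abnormal",
    "dyskeratotic": "abnormal",
    "metaplastic": "normal",
}


@dataclass(frozen=True)
class BlobSpec:
    """Isotropic Gaussian clusters in the unit hypercube.

    ``class_centers`` must lie in the open unit hypercube; generated
    points are clipped to [0, 1].
    """

    n_per_class: int
    n_features: int
    class_centers: tuple
    spread: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_features < 1:
            raise ConfigError("n_per_class and n_features must be positive")
        if self.spread < 0:
            raise ConfigError("spread must be non-negative")
        for c in self.class_centers:
            arr = np.asarray(c, dtype=float)
            if arr.shape != (self.n_features,):
                raise ConfigError(
                    f"center {c} does not have {self.n_features} coordinates"
                )
            if arr.min() <= 0.0 or arr.max() >= 1.0:
                raise ConfigError(
                    f"center {c} must lie strictly inside the unit hypercube"
                )


@dataclass
class DatasetManifest:
    """Ordered (path, raw_label) entries plus a raw-to-binary map."""

    entries: list[tuple[str, str]]
    binary_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {raw for _, raw in self.entries} - set(self.binary_map)
        if missing:
            raise ConfigError(
                f"raw labels without a binary mapping: {sorted(missing)}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def binary_entries(self) -> list[tuple[str, str]]:
        return [(p, self.binary_map[raw]) for p, raw in self.entries]

    def counts(self) -> dict[str, int]:
        """Per-raw-category image counts."""
        return dict(Counter(raw for _, raw in self.entries))

    def binary_counts(self) -> dict[str, int]:
        return dict(Counter(b for _, b in self.binary_entries))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.entries, columns=["path", "raw_label"])
        df["binary_label"] = [self.binary_map[r] for r in df["raw_label"]]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        entries = list(zip(df["path"].astype(str), df["raw_label"].astype(str)))
        bmap = dict(zip(df["raw_label"].astype(str), df["binary_label"].astype(str)))
        return cls(entries=entries, binary_map=bmap)


def generate_blobs(spec: BlobSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw ``n_per_class`` points around each center, clipped to [0,1]^n.

    Returns the feature matrix (flagged normalized, since all points lie
    in the unit cube) and an integer label per row; reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels = [], []
    for cid, center in enumerate(spec.class_centers):
        pts = rng.normal(
            loc=np.asarray(center, dtype=float),
            scale=spec.spread,
            size=(spec.n_per_class, spec.n_features),
        )
        rows.append(np.clip(pts, 0.0, 1.0))
        labels.extend([cid] * spec.n_per_class)
    return (
        FeatureMatrix(values=np.vstack(rows), normalized=True),
        np.asarray(labels, dtype=int),
    )


# ---------------------------------------------------------------------------
# toy cell images

_IMG = 64  # rendered crop side length in pixels


def _render_cell(rng: np.random.Generator, abnormal: bool) -> Image.Image:
    """One synthetic single-cell crop (background, cytoplasm, nucleus)."""
    img = Image.new("RGB", (_IMG, _IMG), (235, 230, 240))
    draw = ImageDraw.Draw(img)
    cx = _IMG / 2 + rng.uniform(-4, 4)
    cy = _IMG / 2 + rng.uniform(-4, 4)

    # cytoplasm disc: generous for normal cells, tighter for abnormal
    cyto_r = rng.uniform(24, 28) if not abnormal else rng.uniform(18, 24)
    draw.ellipse(
        [cx - cyto_r, cy - cyto_r, cx + cyto_r, cy + cyto_r],
        fill=(170 + int(rng.uniform(-10, 10)), 200, 225),
    )

    if abnormal:
        # enlarged irregular nucleus, high nucleus:cytoplasm ratio
        base_r = cyto_r * rng.uniform(0.55, 0.8)
        angles = np.linspace(0.0, 2.0 * np.pi, 12, endpoint=False)
        radii = base_r * (1.0 + rng.uniform(-0.3, 0.3, size=angles.size))
        pts = [
            (cx + r * np.cos(t), cy + r * np.sin(t))
            for r, t in zip(radii, angles)
        ]
        draw.polygon(pts, fill=(90, 60, 130))
    else:
        # small round nucleus
        r = cyto_r * rng.uniform(0.18, 0.3)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=(110, 80, 150))

    # speckle noise so images are not piecewise-constant
    arr = np.asarray(img, dtype=float)
    arr += rng.normal(0.0, 4.0, size=arr.shape)
    return Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))


def generate_toy_images(
    n_per_class: int, seed: int, out_dir: str | Path
) -> DatasetManifest:
    """Render ``n_per_class`` normal and abnormal cell crops as PNG.

    Files land in ``out_dir/<class>/cell_####.png``; the returned
    manifest is sorted lexicographically by path.  Byte-identical for a
    fixed seed.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    entries = []
    for cls, abnormal in (("normal", False), ("abnormal", True)):
        cls_dir = out / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            img = _render_cell(rng, abnormal)
            path = cls_dir / f"cell_{i:04d}.png"
            img.save(path, format="PNG")
            entries.append((str(path), cls))
    entries.sort(key=lambda e: e[0])
    return DatasetManifest(
        entries=entries, binary_map={"normal": "normal", "abnormal": "abnormal"}
    )


# ---------------------------------------------------------------------------
# manifests for real dataset layouts

def _canon(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_").removeprefix("im_")


def build_manifest(
    root: str | Path,
    dataset_style: str = "generic",
    metaplastic_as: str | None = None,
) -> DatasetManifest:
    """Walk ``root/<class_name>/*`` and attach the style's binary map.

    ``dataset_style`` is one of ``herlev``, ``sipakmed`` or ``generic``
    (folder names used verbatim as binary labels).  For Sipakmed,
    ``metaplastic_as`` overrides the default assignment of the benign
    metaplastic category to ``normal``.
    """
    root = Path(root)
    if dataset_style not in ("herlev", "sipakmed", "generic"):
        raise ConfigError(f"unknown dataset style '{dataset_style}'")

    entries: list[tuple[str, str]] = []
    raw_labels: set[str] = set()
    for sub in sorted(p for p in root.iterdir() if p.is_dir()) if root.is_dir() else []:
        raw = _canon(sub.name)
        files = sorted(
            str(f) for f in sub.rglob("*")
            if f.is_file() and f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if files:
            raw_labels.add(raw)
            entries.extend((f, raw) for f in files)
    if not entries:
        raise ConfigError(f"no class folders with images under {root}")
    entries.sort(key=lambda e: e[0])

    if dataset_style == "herlev":
        bmap = dict(HERLEV_BINARY_MAP)
    elif dataset_style == "sipakmed":
        bmap = dict(SIPAKMED_BINARY_MAP)
        if metaplastic_as is not None:
            if metaplastic_as not in ("normal", "abnormal"):
                raise ConfigError("metaplastic_as must be 'normal' or 'abnormal'")
            bmap["metaplastic"] = metaplastic_as
    else:
        bmap = {raw: raw for raw in raw_labels}

    unmapped = sorted(raw_labels - set(bmap))
    if unmapped:
        raise ConfigError(
            f"folder names without a {dataset_style} mapping: {unmapped}"
        )
    return DatasetManifest(entries=entries, binary_map=bmap)
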