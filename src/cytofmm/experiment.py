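"""Experiment driver: extract -> normalize -> split -> train -> evaluate.

Two protocols are provided on top of one shared, seeded pipeline:

* ``run_theta_sweep`` trains the fuzzy min-max network once per theta on
  a grid (default 0, 0.1, ..., 1.0) over a single fixed split, and
  reports the five screening metrics plus the hyperbox count per theta.
  The same shuffled presentation order is reused for every theta so the
  sweep isolates theta's effect.

* ``run_bench`` runs the seven conventional baselines and the best-theta
  fuzzy min-max network on byte-identical splits, one result row per
  classifier.

All randomness (split, presentation order, baseline seeds) derives from
the config seed; reports are CSV plus a rendered text table, and the
per-sample predictions behind every report row are persisted so any
cell can be re-derived.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import BASELINE_NAMES, BaselineSpec, fit_predict, is_analogue
from .classifier import predict, train
from .errors import ConfigError
from .extractors import extract_features, get_extractor_spec
from .features import FeatureMatrix, apply_normalizer, fit_normalizer, load_feature_csv
from .metrics import confusion, metrics
from .synthetic import BlobSpec, DatasetManifest, build_manifest, generate_blobs, generate_toy_images

__all__ = ["ExperimentConfig", "run_theta_sweep", "run_bench", "prepare_data"]

logger = logging.getLogger("cytofmm")

DEFAULT_THETA_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs, loadable from YAML/JSON.

    ``dataset`` is a block with a ``type`` of ``blobs``, ``toy_images``,
    ``manifest`` or ``csv`` plus type-specific keys.  ``positive_class``
    names the label treated as positive (screening: the abnormal one).
    """

    dataset: dict
    extractor: str = "toy"
    extractor_dim: int = 24
    split_ratio: float = 0.7
    split_seed: int = 0
    stratified: bool = True
    theta_grid: tuple = DEFAULT_THETA_GRID
    gamma: float = 1.0
    baselines: tuple = tuple(BaselineSpec(n) for n in BASELINE_NAMES)
    normalize_baselines: bool = False
    positive_class: str | int = "abnormal"
    output_dir: str = "cytofmm_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError(f"split ratio must be in (0,1), got {self.split_ratio}")
        for t in self.theta_grid:
            if not 0.0 <= t <= 1.0:
                raise ConfigError(f"theta {t} outside [0, 1]")
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        baselines = tuple(
            BaselineSpec(b["name"], b.get("params", {}), b.get("seed", 0))
            if isinstance(b, dict) else BaselineSpec(b)
            for b in doc.pop("baselines", BASELINE_NAMES)
        )
        theta_grid = tuple(doc.pop("theta_grid", DEFAULT_THETA_GRID))
        return cls(baselines=baselines, theta_grid=theta_grid, **doc)


def prepare_data(config: ExperimentConfig):
    """Resolve the dataset block and return train/test features + labels.

    Features for the fuzzy min-max network are min-max normalized with
    training-set statistics; raw features are returned alongside for
    baselines (configurable).  The training rows are shuffled once with
    the split seed so presentation order is reproducible.
    """
    from sklearn.model_selection import train_test_split

    block = dict(config.dataset)
    kind = block.pop("type", "blobs")
    if kind == "blobs":
        spec = BlobSpec(
            n_per_class=block.get("n_per_class", 100),
            n_features=block.get("n_features", 2),
            class_centers=tuple(
                tuple(c) for c in block.get(
                    "class_centers", [[0.3, 0.3], [0.7, 0.7]]
                )
            ),
            spread=block.get("spread", 0.05),
            seed=block.get("seed", config.split_seed),
        )
        fm, labels = generate_blobs(spec)
    elif kind == "toy_images":
        out_dir = block.get("dir", str(Path(config.output_dir) / "toy_images"))
        manifest = generate_toy_images(
            n_per_class=block.get("n_per_class", 100),
            seed=block.get("seed", config.split_seed),
            out_dir=out_dir,
        )
        spec = get_extractor_spec(config.extractor, config.extractor_dim)
        fm, raw = extract_features(manifest.binary_entries, spec)
        labels = raw
    elif kind == "manifest":
        manifest = (
            DatasetManifest.from_csv(block["path"])
            if str(block["path"]).endswith(".csv")
            else build_manifest(block["path"], block.get("style", "generic"))
        )
        spec = get_extractor_spec(config.extractor, config.extractor_dim)
        fm, labels = extract_features(manifest.binary_entries, spec)
    elif kind == "csv":
        fm, labels = load_feature_csv(block["path"])
    else:
        raise ConfigError(f"unknown dataset type '{kind}'")

    idx = np.arange(fm.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=config.split_ratio,
        random_state=config.split_seed,
        stratify=labels if config.stratified else None,
    )
    # one seeded shuffle fixes FMMN presentation order across all thetas
    rng = np.random.default_rng(config.split_seed)
    rng.shuffle(train_idx)

    raw_train = FeatureMatrix(fm.values[train_idx], list(fm.feature_names))
    raw_test = FeatureMatrix(fm.values[test_idx], list(fm.feature_names))
    state = fit_normalizer(raw_train)
    norm_train = apply_normalizer(raw_train, state)
    norm_test = apply_normalizer(raw_test, state)
    y = np.asarray(labels)
    return {
        "raw_train": raw_train,
        "raw_test": raw_test,
        "norm_train": norm_train,
        "norm_test": norm_test,
        "y_train": y[train_idx],
        "y_test": y[test_idx],
        "train_idx": train_idx,
        "test_idx": test_idx,
    }


def _evaluate(y_true, y_pred, positive_class) -> dict:
    rep = metrics(confusion(y_true, y_pred, positive_class))
    return rep.as_dict()


def _render_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def run_theta_sweep(config: ExperimentConfig, data: dict | None = None) -> pd.DataFrame:
    """Train/evaluate the fuzzy min-max net once per theta on a fixed split.

    Returns one row per theta with the five metrics and the hyperbox
    count; writes ``sweep.csv``, ``sweep.txt`` and per-theta predictions
    under the config's output directory.
    """
    data = data or prepare_data(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows, all_preds = [], {}
    for theta in config.theta_grid:
        model = train(data["norm_train"], data["y_train"], theta=theta, gamma=config.gamma)
        y_pred = predict(model, data["norm_test"])
        row = {"theta": theta, "n_hyperboxes": model.n_hyperboxes}
        row.update(_evaluate(data["y_test"], y_pred, config.positive_class))
        rows.append(row)
        all_preds[f"fmmn_theta_{theta}"] = y_pred
        logger.info("theta=%.1f boxes=%d acc=%.4f", theta, model.n_hyperboxes, row["accuracy"])

    df = pd.DataFrame(rows)
    df.to_csv(out / "sweep.csv", index=False)
    (out / "sweep.txt").write_text(_render_table(df) + "\n")
    _save_predictions(out / "sweep_predictions.csv", data, all_preds)
    return df


def run_bench(config: ExperimentConfig, data: dict | None = None) -> pd.DataFrame:
    """Compare the seven baselines and the best-theta fuzzy min-max net.

    All classifiers see byte-identical splits.  Baselines consume raw
    features by default (normalization is the fuzzy net's own
    prerequisite); set ``normalize_baselines`` to share the normalized
    view.  Returns one row per classifier, FMMN last.
    """
    data = data or prepare_data(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    b_train = data["norm_train"] if config.normalize_baselines else data["raw_train"]
    b_test = data["norm_test"] if config.normalize_baselines else data["raw_test"]

    rows, all_preds = [], {}
    for spec in config.baselines:
        y_pred = fit_predict(spec, b_train, data["y_train"], b_test)
        row = {"model": spec.name, "analogue": is_analogue(spec.name), "theta": np.nan}
        row.update(_evaluate(data["y_test"], y_pred, config.positive_class))
        rows.append(row)
        all_preds[spec.name] = y_pred

    sweep = run_theta_sweep(config, data)
    best = sweep.loc[sweep["accuracy"].idxmax()]
    model = train(
        data["norm_train"], data["y_train"],
        theta=float(best["theta"]), gamma=config.gamma,
    )
    y_pred = predict(model, data["norm_test"])
    row = {"model": "fmmn", "analogue": False, "theta": float(best["theta"])}
    row.update(_evaluate(data["y_test"], y_pred, config.positive_class))
    rows.append(row)
    all_preds["fmmn"] = y_pred

    df = pd.DataFrame(rows)
    df.to_csv(out / "bench.csv", index=False)
    (out / "bench.txt").write_text(_render_table(df) + "\n")
    _save_predictions(out / "bench_predictions.csv", data, all_preds)

    log = {
        "seed": config.split_seed,
        "train_size": int(len(data["y_train"])),
        "test_size": int(len(data["y_test"])),
        "extractor": config.extractor,
        "gamma": config.gamma,
        "versions": _versions(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return df


def _save_predictions(path: Path, data: dict, preds: dict) -> None:
    df = pd.DataFrame({"sample_index": data["test_idx"], "true_label": data["y_test"]})
    for name, y in preds.items():
        df[name] = y
    df.to_csv(path, index=False)


def _versions() -> dict:
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
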