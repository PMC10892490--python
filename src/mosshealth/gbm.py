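"""Stage-1 per-pixel gradient-boosted-tree classifier.

Assembles a pixel x feature table from a band stack (raw bands, spectral
indices, windowed texture statistics), trains an XGBoost multi-class
model with the workflow's tuned hyperparameters (depth 10, learning rate
0.02, 250 estimators, subsample 0.8, colsample_bytree 0.8), predicts
5-class probability planes in 700x700-pixel batches, and ranks features
by gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb

from .bands import BandStack
from .features import FeatureSpec, FeatureCube, build_feature_cube, DEFAULT_SPEC
from .tiling import make_grid

__all__ = [
    "GbmConfig",
    "GbmModel",
    "build_feature_table",
    "train_gbm",
    "predict_gbm",
    "predict_rows",
    "save_model",
    "load_model",
]

N_CLASSES = 5


@dataclass(frozen=True)
class GbmConfig:
    """Tuned hyperparameters of the stage-1 classifier."""

    max_depth: int = 10
    learning_rate: float = 0.02
    n_estimators: int = 250
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    gamma: float = 0.0
    reg_alpha: float = 0.0
    reg_lambda: float = 1.0
    seed: int = 0
    class_weighting: bool = False  # optional inverse-frequency weights
    prediction_tile: int = 700

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GbmConfig":
        return cls(**d)

    def xgb_params(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "gamma": self.gamma,
            "alpha": self.reg_alpha,
            "lambda": self.reg_lambda,
            "objective": "multi:softprob",
            "num_class": N_CLASSES,
            "tree_method": "hist",
            "seed": self.seed,
            "nthread": 1,
        }


def build_feature_table(
    stack: BandStack,
    spec: FeatureSpec = DEFAULT_SPEC,
    labels: np.ndarray | None = None,
    cube: FeatureCube | None = None,
):
    """Flatten feature planes to a (pixels x features) matrix.

    In training mode (``labels`` given) only labeled (non-zero), valid
    pixels produce rows and the matching label vector is returned; in
    prediction mode every valid pixel produces a row.  Rows follow
    row-major pixel order; the boolean selection mask is returned for
    scattering predictions back into planes.

    Returns ``(rows, y_or_None, mask, feature_names)``.
    """
    if cube is None:
        cube = build_feature_cube(stack, spec)
    valid = ~cube.nodata_mask
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != cube.shape:
            raise ValueError(f"labels {labels.shape} misaligned with cube {cube.shape}")
        sel = valid & (labels > 0)
    else:
        sel = valid
    if not sel.any():
        raise ValueError("no valid pixels to tabulate (all nodata or unlabeled)")
    rows = cube.planes[:, sel].T  # row-major order since sel indexes row-major
    y = labels[sel].astype(np.int64) if labels is not None else None
    assert np.isfinite(rows).all()
    return rows, y, sel, list(cube.names)


@dataclass
class GbmModel:
    """Fitted booster plus the feature spec it was trained with."""

    booster: xgb.Booster
    spec: FeatureSpec
    feature_names: list[str]
    config: GbmConfig
    classes: np.ndarray = field(default_factory=lambda: np.arange(1, N_CLASSES + 1))

    def importance(self) -> pd.Series:
        """Gain-based feature importance, descending."""
        gains = self.booster.get_score(importance_type="gain")
        s = pd.Series({n: gains.get(n, 0.0) for n in self.feature_names}, dtype=float)
        return s.sort_values(ascending=False)


def train_gbm(
    rows: np.ndarray,
    y: np.ndarray,
    cfg: GbmConfig = GbmConfig(),
    spec: FeatureSpec = DEFAULT_SPEC,
    feature_names: list[str] | None = None,
) -> GbmModel:
    """Fit the stage-1 classifier on a feature table.

    ``y`` holds class IDs 1..5; at least two classes must be present.
    The booster always emits 5-class probability vectors, even when the
    training labels miss a class.  Reproducible given ``cfg.seed``.
    """
    rows = np.asarray(rows, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError(f"need >= 2 classes to train; labels contain only {present}")
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(rows.shape[1])]
    weights = None
    if cfg.class_weighting:
        freq = np.bincount(y - 1, minlength=N_CLASSES).astype(float)
        inv = np.where(freq > 0, 1.0 / np.maximum(freq, 1.0), 0.0)
        weights = inv[y - 1]
        weights *= len(y) / weights.sum()
    dtrain = xgb.DMatrix(rows, label=y - 1, weight=weights, feature_names=names)
    booster = xgb.train(cfg.xgb_params(), dtrain, num_boost_round=cfg.n_estimators)
    return GbmModel(booster=booster, spec=spec, feature_names=names, config=cfg)


def predict_rows(model: GbmModel, rows: np.ndarray) -> np.ndarray:
    """(n, 5) class probabilities for a feature table."""
    d = xgb.DMatrix(np.asarray(rows, dtype=np.float64), feature_names=model.feature_names)
    return model.booster.predict(d)


def predict_gbm(
    model: GbmModel,
    stack: BandStack,
    tile: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel probabilistic segmentation of a full stack.

    Inference runs tile-by-tile (default 700x700 windows, no overlap —
    the model is per-pixel, so tile boundaries cannot change outputs).
    Texture features are computed once over the full raster so windowed
    statistics see no tile seams.  Returns ``(hard, soft)``; nodata
    pixels get hard label 0 and zero probability.
    """
    cube = build_feature_cube(stack, model.spec)
    if cube.names != model.feature_names:
        missing = [n for n in model.feature_names if n not in cube.names]
        raise ValueError(
            f"feature spec mismatch: model expects {model.feature_names}, "
            f"missing from input: {missing or 'none (order differs)'}"
        )
    h, w = cube.shape
    t = tile or model.config.prediction_tile
    soft = np.zeros((N_CLASSES, h, w))
    grid = make_grid(h, w, (min(t, h), min(t, w)), overlap=0.0)
    for (r, c, th, tw) in grid.windows:
        sub_valid = ~cube.nodata_mask[r : r + th, c : c + tw]
        if not sub_valid.any():
            continue
        rows = cube.planes[:, r : r + th, c : c + tw][:, sub_valid].T
        probs = predict_rows(model, rows)
        block = np.zeros((N_CLASSES, th, tw))
        block[:, sub_valid] = probs.T
        soft[:, r : r + th, c : c + tw] = block
    hard = np.where(cube.nodata_mask, 0, np.argmax(soft, axis=0) + 1)
    return hard.astype(np.int64), soft


def save_model(model: GbmModel, path) -> None:
    """Serialize the booster to JSON with feature spec and config embedded."""
    raw = model.booster.save_raw(raw_format="json").decode()
    payload = {
        "booster": json.loads(raw),
        "spec": model.spec.to_dict(),
        "feature_names": model.feature_names,
        "config": model.config.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> GbmModel:
    with open(path) as fh:
        payload = json.load(fh)
    booster = xgb.Booster()
    booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
    names = list(payload["feature_names"])
    booster.feature_names = names
    return GbmModel(
        booster=booster,
        spec=FeatureSpec.from_dict(payload["spec"]),
        feature_names=names,
        config=GbmConfig.from_dict(payload["config"]),
    )
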