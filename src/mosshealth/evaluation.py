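"""Segmentation evaluation: confusion matrices, per-class metrics, k-fold
cross-validation and class-area reports.

Per-class metrics follow the one-vs-rest counting convention:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (FP + 2 TP + FN)
    IoU       = TP / (TP + FP + FN)

Zero-denominator cases yield 0 with an explicit ``undefined`` flag instead
of NaN, so report schemas stay stable when a class has no support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "CvResult",
    "confusion",
    "metrics",
    "kfold",
    "area_report",
]

N_CLASSES = 5


@dataclass
class ConfusionMatrix:
    """Counts over evaluated pixels; rows = true class, cols = predicted."""

    counts: np.ndarray  # (C, C) int
    class_ids: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        safe = np.where(rows == 0, 1.0, rows)
        return self.counts / safe

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def tn(self) -> np.ndarray:
        return self.n - self.tp() - self.fp() - self.fn()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_ids), columns=list(self.class_ids))


def confusion(truth: np.ndarray, pred: np.ndarray, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    """Confusion counts between aligned label rasters, ignoring truth==0."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    sel = truth > 0
    t = truth[sel].astype(np.int64) - 1
    p = pred[sel].astype(np.int64) - 1
    # predictions of 0 (nodata) fall outside 0..C-1 and are counted nowhere
    ok = (p >= 0) & (p < n_classes)
    counts = np.bincount(t[ok] * n_classes + p[ok], minlength=n_classes * n_classes)
    return ConfusionMatrix(
        counts=counts.reshape(n_classes, n_classes),
        class_ids=tuple(range(1, n_classes + 1)),
    )


@dataclass
class EvalReport:
    """Per-class precision/recall/F1/IoU plus aggregates and areas."""

    class_ids: tuple[int, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    iou: np.ndarray
    support: np.ndarray
    undefined: np.ndarray  # per-class flag: some metric had a zero denominator
    confusion: ConfusionMatrix = None
    area: dict = field(default_factory=dict)

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def weighted_f1(self) -> float:
        w = self.support / max(1, self.support.sum())
        return float((self.f1 * w).sum())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def accuracy(self) -> float:
        cm = self.confusion
        return float(cm.tp().sum() / max(1, cm.n))

    def to_frame(self, class_names: list[str] | None = None) -> pd.DataFrame:
        idx = class_names if class_names is not None else list(self.class_ids)
        return pd.DataFrame(
            {
                "Precision": np.round(self.precision, 4),
                "Recall": np.round(self.recall, 4),
                "F1-Score": np.round(self.f1, 4),
                "IoU": np.round(self.iou, 4),
                "Support": self.support,
            },
            index=idx,
        )

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(cid): {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "iou": float(self.iou[i]),
                    "support": int(self.support[i]),
                    "undefined": bool(self.undefined[i]),
                }
                for i, cid in enumerate(self.class_ids)
            },
            "macro_f1": self.macro_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "area": self.area,
        }


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bad = den == 0
    return np.where(bad, 0.0, num / np.where(bad, 1, den)), bad


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Per-class precision/recall/F1/IoU from a confusion matrix."""
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    precision, bad_p = _safe_ratio(tp, tp + fp)
    recall, bad_r = _safe_ratio(tp, tp + fn)
    f1, bad_f = _safe_ratio(2.0 * tp, fp + 2.0 * tp + fn)
    iou, bad_i = _safe_ratio(tp, tp + fp + fn)
    return EvalReport(
        class_ids=cm.class_ids,
        precision=precision,
        recall=recall,
        f1=f1,
        iou=iou,
        support=cm.counts.sum(axis=1),
        undefined=bad_p | bad_r | bad_f | bad_i,
        confusion=cm,
    )


def evaluate(truth: np.ndarray, pred: np.ndarray, n_classes: int = N_CLASSES) -> EvalReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(truth, pred, n_classes=n_classes))


@dataclass
class CvResult:
    k: int
    fold_accuracy: list[float]
    fold_loss: list[float] | None
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))


def kfold(
    rows: np.ndarray,
    y: np.ndarray,
    k: int,
    trainer,
    fold_unit: str = "pixel",
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation of a pixel classifier.

    ``trainer(X_tr, y_tr, X_te, y_te) -> (accuracy, loss_or_None)`` runs
    one fold.  With ``fold_unit="tile"`` samples are assigned to folds by
    their ``groups`` id (all pixels of a tile land in the same fold),
    which avoids the optimistic bias of splitting spatially correlated
    neighbours across folds; ``fold_unit="pixel"`` stratifies sample rows
    directly.
    """
    rows = np.asarray(rows)
    y = np.asarray(y)
    if k < 2:
        raise ValueError(f"k must be >= 2; got {k}")
    if k > len(y):
        raise ValueError(f"k={k} exceeds number of samples {len(y)}")
    if fold_unit not in ("pixel", "tile"):
        raise ValueError(f"fold_unit must be pixel|tile; got {fold_unit!r}")

    if fold_unit == "tile":
        if groups is None:
            raise ValueError("tile fold unit requires a groups array")
        uniq = np.unique(groups)
        if k > len(uniq):
            raise ValueError(f"k={k} exceeds number of tiles {len(uniq)}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(uniq)
        fold_of_group = {g: i % k for i, g in enumerate(order)}
        fold_idx = np.array([fold_of_group[g] for g in groups])
        splits = [
            (np.flatnonzero(fold_idx != f), np.flatnonzero(fold_idx == f)) for f in range(k)
        ]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(rows, y))

    accs, losses = [], []
    for tr, te in splits:
        acc, loss = trainer(rows[tr], y[tr], rows[te], y[te])
        accs.append(float(acc))
        losses.append(loss)
    has_loss = all(l is not None for l in losses)
    return CvResult(
        k=k,
        fold_accuracy=accs,
        fold_loss=[float(l) for l in losses] if has_loss else None,
        seed=seed,
    )


def area_report(
    seg: np.ndarray,
    pixel_area: float,
    region: np.ndarray | None = None,
    n_classes: int = N_CLASSES,
) -> dict:
    """Per-class surface area (m^2) and percentage over a target region.

    ``pixel_area`` is the ground area of one pixel in m^2 (GSD squared);
    ``region`` optionally restricts the tally.  Percentages are over the
    labeled (non-zero) pixels of the region; unlabeled area is reported
    separately.
    """
    if pixel_area <= 0:
        raise ValueError(f"pixel_area must be positive; got {pixel_area}")
    seg = np.asarray(seg)
    if region is None:
        region = np.ones(seg.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty evaluation region")
    vals = seg[region]
    labeled = vals[vals > 0]
    counts = np.bincount(labeled, minlength=n_classes + 1)[1:]
    total_labeled = counts.sum()
    out = {
        "region_area_m2": float(region.sum() * pixel_area),
        "unlabeled_area_m2": float((len(vals) - total_labeled) * pixel_area),
        "classes": {},
    }
    for cid in range(1, n_classes + 1):
        cnt = int(counts[cid - 1])
        out["classes"][cid] = {
            "pixels": cnt,
            "area_m2": float(cnt * pixel_area),
            "percent": float(100.0 * cnt / total_labeled) if total_labeled else 0.0,
        }
    return out
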