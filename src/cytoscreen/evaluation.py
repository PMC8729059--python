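"""Screening performance metrics: per-class one-vs-rest statistics from a
confusion matrix, ordinal cutoff recall, and detection mAP.

The per-class metrics follow the standard binary decomposition of a
multi-class confusion matrix (rows = true class, columns = predicted class):
for class k,

    TP = cm[k, k]            FN = row-k sum - TP
    FP = col-k sum - TP      TN = total - TP - FP - FN

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-measure = 2 * precision * recall / (precision + recall)

Zero-denominator ratios are reported as 0 with a flag rather than raising, so
empty classes cannot crash batch evaluation.  Macro averages are unweighted
means over the classes.

``cutoff_recall`` answers the screening question "of everything truly at or
above severity X, what fraction was called at or above X?" -- the clinically
decisive figure for a triage cutoff such as ASC-US.

``detection_map`` scores box detections the PASCAL way: greedy confidence-
ranked matching at a fixed IoU threshold per class, average precision as the
area under the stepwise (all-points) precision-recall curve, and mAP as the
macro mean over classes with at least one ground-truth box.

Two reference confusion matrices from a published two-stage cervical
screening evaluation (stage 1: detection; stage 2: classification) ship with
the package as regression fixtures; see :func:`load_reference_matrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .boxes import BoundingBox, iou
from .errors import DataError
from .ordinal import CLASS_NAMES, Bethesda

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "ClassMetrics",
    "MetricsReport",
    "DetectionEvalResult",
    "one_vs_rest",
    "metrics",
    "report",
    "cutoff_recall",
    "detection_map",
    "load_reference_matrix",
    "round_half_up_percent",
]


def round_half_up_percent(x: float, decimals: int = 1) -> float:
    """Display rounding: value in [0,1] to percent, half-up (so 0.705 -> 70.5)."""
    scale = 10.0**decimals
    return float(np.floor(x * 100.0 * scale + 0.5) / scale)


@dataclass(frozen=True)
class ConfusionMatrix:
    """c x c integer counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] == 0:
            raise DataError("confusion matrix is empty")
        if np.any(counts < 0):
            raise ValueError("confusion-matrix counts must be non-negative")
        if len(self.class_order) != counts.shape[0]:
            raise ValueError("class_order length must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_order", tuple(self.class_order))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_index(self, k: str | Bethesda | int) -> int:
        """0-based row/column index of a class given by name, enum or index."""
        if isinstance(k, str):
            try:
                return self.class_order.index(k)
            except ValueError:
                raise IndexError(
                    f"class {k!r} not in {self.class_order}"
                ) from None
        idx = int(k) - 1 if isinstance(k, Bethesda) else int(k)
        if not 0 <= idx < self.n_classes:
            raise IndexError(f"class index {idx} out of range")
        return idx

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise DataError(f"{path}: row and column class names differ")
        return cls(counts=df.to_numpy(), class_order=tuple(df.columns))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        ).to_csv(path)


def load_reference_matrix(stage: int) -> ConfusionMatrix:
    """Bundled reference confusion matrix for stage 1 (detection) or 2
    (classification) of the two-stage screening evaluation."""
    name = {1: "detection_confusion.csv", 2: "classification_confusion.csv"}.get(stage)
    if name is None:
        raise ValueError(f"stage must be 1 or 2, got {stage}")
    with resources.as_file(resources.files("cytoscreen.data") / name) as p:
        return ConfusionMatrix.from_csv(p)


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest tallies for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def one_vs_rest(cm: ConfusionMatrix, k: str | Bethesda | int) -> BinaryCounts:
    """Collapse a multi-class matrix to binary counts for class ``k``."""
    i = cm.class_index(k)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return BinaryCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    #: names of ratios whose denominator was zero (reported as 0)
    undefined: tuple[str, ...] = ()


def metrics(counts: BinaryCounts) -> ClassMetrics:
    """Accuracy, precision, recall and F-measure from binary counts.

    A ratio with zero denominator is returned as 0 and flagged in
    ``undefined`` instead of raising.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    rec = ratio(counts.tp, counts.tp + counts.fn, "recall")
    if prec + rec == 0:
        undefined.append("f_measure")
        f = 0.0
    else:
        f = 2.0 * prec * rec / (prec + rec)
    return ClassMetrics(
        accuracy=acc, precision=prec, recall=rec, f_measure=f,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metrics plus unweighted macro averages."""

    per_class: dict[str, ClassMetrics]
    macro_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f_measure: float

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        rows = {}
        for name, m in self.per_class.items():
            rows[name] = [m.accuracy, m.precision, m.recall, m.f_measure]
        rows["Average"] = [
            self.macro_accuracy,
            self.macro_precision,
            self.macro_recall,
            self.macro_f_measure,
        ]
        df = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["accuracy", "precision", "recall", "f_measure"],
        )
        if percent:
            df = df.map(round_half_up_percent)
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_class": {
                name: {
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f_measure": m.f_measure,
                    "undefined": list(m.undefined),
                }
                for name, m in self.per_class.items()
            },
            "macro": {
                "accuracy": self.macro_accuracy,
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f_measure": self.macro_f_measure,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Full per-class + macro metrics report for a confusion matrix."""
    per_class = {
        name: metrics(one_vs_rest(cm, name)) for name in cm.class_order
    }
    vals = list(per_class.values())
    return MetricsReport(
        per_class=per_class,
        macro_accuracy=float(np.mean([m.accuracy for m in vals])),
        macro_precision=float(np.mean([m.precision for m in vals])),
        macro_recall=float(np.mean([m.recall for m in vals])),
        macro_f_measure=float(np.mean([m.f_measure for m in vals])),
    )


def cutoff_recall(cm: ConfusionMatrix, cutoff: str | Bethesda | int) -> float:
    """Recall of the binary screen {true >= cutoff} vs {predicted >= cutoff}.

    TP are cells with true class and predicted class both at or above the
    cutoff; FN those with true at/above but predicted below.
    """
    i = cm.class_index(cutoff)
    tp = int(cm.counts[i:, i:].sum())
    fn = int(cm.counts[i:, :i].sum())
    if tp + fn == 0:
        return 0.0
    return tp / (tp + fn)


# ---------------------------------------------------------------------------
# detection mAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionEvalResult:
    per_class_ap: dict[str, float]
    map: float
    iou_threshold: float
    #: classes present in the ground truth (the mAP denominator)
    evaluated_classes: tuple[str, ...] = ()


def _average_precision(matched: np.ndarray, conf: np.ndarray, n_gt: int) -> float:
    """All-points AP: area under the stepwise precision-recall curve."""
    if n_gt == 0:
        return 0.0
    if matched.size == 0:
        return 0.0
    order = np.argsort(-conf, kind="stable")
    tp = matched[order].astype(float)
    fp = 1.0 - tp
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # envelope precision, then sum rectangle areas at recall steps
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def detection_map(
    predictions: dict[str, list[BoundingBox]],
    ground_truth: dict[str, list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> DetectionEvalResult:
    """Mean average precision over classes with ground truth.

    ``predictions`` and ``ground_truth`` map image ids to box lists;
    prediction confidences drive the ranking (mAP depends only on their
    order).  Matching is greedy per image in descending confidence at the
    given IoU threshold; each ground-truth box matches at most one detection.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"IoU threshold must lie in (0, 1), got {iou_threshold}")
    gt_classes = sorted(
        {b.class_label for boxes in ground_truth.values() for b in boxes if b.class_label},
        key=int,
    )
    if not gt_classes:
        raise DataError("no ground-truth boxes to evaluate against")
    per_class_ap: dict[str, float] = {}
    for cls in gt_classes:
        n_gt = sum(
            1 for boxes in ground_truth.values() for b in boxes if b.class_label is cls
        )
        matched_flags: list[bool] = []
        confs: list[float] = []
        for image_id, preds in predictions.items():
            gts = [
                b for b in ground_truth.get(image_id, []) if b.class_label is cls
            ]
            taken = [False] * len(gts)
            cls_preds = sorted(
                (p for p in preds if p.class_label is cls),
                key=lambda p: -p.confidence,
            )
            for p in cls_preds:
                best, best_iou = -1, iou_threshold
                for j, g in enumerate(gts):
                    if taken[j]:
                        continue
                    ov = iou(p, g)
                    if ov >= best_iou:
                        best, best_iou = j, ov
                if best >= 0:
                    taken[best] = True
                    matched_flags.append(True)
                else:
                    matched_flags.append(False)
                confs.append(p.confidence)
        per_class_ap[cls.label] = _average_precision(
            np.asarray(matched_flags, dtype=bool), np.asarray(confs, dtype=float), n_gt
        )
    return DetectionEvalResult(
        per_class_ap=per_class_ap,
        map=float(np.mean(list(per_class_ap.values()))),
        iou_threshold=iou_threshold,
        evaluated_classes=tuple(c.label for c in gt_classes),
    )
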