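"""Two-step screening: detect atypical clusters, classify each crop, and call
the image NILM when nothing is detected.

Step 1 proposes bounding boxes around atypical cell clusters with a coarse
class and a confidence.  Step 2 crops each surviving box (plus a margin),
runs the ordinal classifier on the crop, and replaces the coarse class with
the classifier's argmax.  Classification refines detection output: the number
of detections never changes between stages, only their labels.

An image with zero detections above the confidence threshold is called NILM
-- normality by absence, which is exactly how a detector trained only on
atypical classes expresses "nothing suspicious here".  Otherwise the image-
level call is the maximum severity among the refined boxes, a deliberately
conservative aggregation for a screening setting.

``run_batch`` scores a manifest of annotated images and accumulates one
confusion matrix per stage (rows = true class, columns = predicted).
Detections are matched to ground-truth boxes greedily by confidence at
IoU >= 0.5 (the community-standard rule); an unmatched ground truth whose
best detection overlap is still >= 0.1 is tallied under that detection's
predicted class, otherwise it is counted as missed and reported separately.
Unmatched detections count as false positives against the NILM row, and a
truly normal image with no detections scores one NILM/NILM unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import CellImage, load_image
from .backends import ClassifierBackend, DetectorBackend
from .boxes import BoundingBox, iou, read_darknet
from .errors import DataError
from .evaluation import ConfusionMatrix
from .ordinal import CLASS_NAMES, NUM_CLASSES, Bethesda

__all__ = ["ImageResult", "BatchResult", "crop_with_margin", "run_two_step", "run_batch"]

#: Fraction of box width/height added on each side before classification.
DEFAULT_CROP_MARGIN = 0.10

#: Detector confidence below which boxes are discarded.
DEFAULT_CONF_THRESHOLD = 0.25


def crop_with_margin(
    img: CellImage, box: BoundingBox, margin: float = DEFAULT_CROP_MARGIN
) -> CellImage:
    """Extract the box plus ``margin`` x size on each side, clipped to frame."""
    h, w = img.pixels.shape[:2]
    x0, y0, x1, y1 = box.corners
    mx, my = box.w * margin, box.h * margin
    px0 = max(0, int(np.floor((x0 - mx) * w)))
    py0 = max(0, int(np.floor((y0 - my) * h)))
    px1 = min(w, int(np.ceil((x1 + mx) * w)))
    py1 = min(h, int(np.ceil((y1 + my) * h)))
    px1 = max(px1, px0 + 1)
    py1 = max(py1, py0 + 1)
    return CellImage(
        pixels=np.ascontiguousarray(img.pixels[py0:py1, px0:px1]),
        id=f"{img.id}__crop_{px0}_{py0}",
    )


@dataclass(frozen=True)
class ImageResult:
    """Outcome of the two-step pipeline on one image."""

    image_id: str
    detections: tuple[BoundingBox, ...]
    refined: tuple[tuple[BoundingBox, np.ndarray, Bethesda], ...]

    def __post_init__(self) -> None:
        if len(self.refined) != len(self.detections):
            raise ValueError("every detection must have exactly one refined entry")

    @property
    def image_call(self) -> Bethesda:
        """NILM when nothing was detected, else the maximum refined severity."""
        if not self.refined:
            return Bethesda.NILM
        return max((final for _, _, final in self.refined), key=int)


def run_two_step(
    img: CellImage,
    detector: DetectorBackend,
    classifier: ClassifierBackend,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    crop_margin: float = DEFAULT_CROP_MARGIN,
) -> ImageResult:
    """Detect, filter by confidence, crop, classify, and aggregate."""
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError(f"conf_threshold must lie in [0, 1], got {conf_threshold}")
    try:
        raw = detector.detect(img)
    except Exception as exc:
        raise RuntimeError(f"detector failed on image {img.id!r}: {exc}") from exc
    kept = tuple(b for b in raw if b.confidence >= conf_threshold)
    refined = []
    for box in kept:
        crop = crop_with_margin(img, box, crop_margin)
        try:
            probs = np.asarray(classifier.classify(crop), dtype=float)
        except Exception as exc:
            raise RuntimeError(
                f"classifier failed on image {img.id!r}: {exc}"
            ) from exc
        final = Bethesda(int(np.argmax(probs)) + 1)
        refined.append((box, probs, final))
    return ImageResult(image_id=img.id, detections=kept, refined=tuple(refined))


@dataclass(frozen=True)
class BatchResult:
    """Per-box results table plus per-stage confusion matrices (when scored)."""

    results: pd.DataFrame
    stage1: ConfusionMatrix | None
    stage2: ConfusionMatrix | None
    #: per-class counts of ground-truth boxes with no overlapping detection
    missed: dict[str, int] | None
    errors: tuple[str, ...] = ()


def _match_and_accumulate(
    result: ImageResult,
    gt_boxes: list[BoundingBox],
    cm1: np.ndarray,
    cm2: np.ndarray,
    missed: dict[str, int],
) -> None:
    nilm = 0  # row index of NILM
    dets = sorted(
        range(len(result.refined)),
        key=lambda i: -result.detections[i].confidence,
    )
    gt_taken = [False] * len(gt_boxes)
    det_matched = [False] * len(result.refined)
    pairs: list[tuple[int, int]] = []
    for di in dets:
        box = result.detections[di]
        best, best_iou = -1, 0.5
        for gi, g in enumerate(gt_boxes):
            if gt_taken[gi]:
                continue
            ov = iou(box, g)
            if ov >= best_iou:
                best, best_iou = gi, ov
        if best >= 0:
            gt_taken[best] = True
            det_matched[di] = True
            pairs.append((best, di))
    for gi, di in pairs:
        true = int(gt_boxes[gi].class_label) - 1
        cm1[true, int(result.detections[di].class_label) - 1] += 1
        cm2[true, int(result.refined[di][2]) - 1] += 1
    for gi, g in enumerate(gt_boxes):
        if gt_taken[gi]:
            continue
        # weak-overlap fallback: credit the overlapping detection's column
        best, best_iou = -1, 0.1
        for di in range(len(result.refined)):
            ov = iou(result.detections[di], g)
            if ov >= best_iou:
                best, best_iou = di, ov
        true = int(g.class_label) - 1
        if best >= 0:
            cm1[true, int(result.detections[best].class_label) - 1] += 1
            cm2[true, int(result.refined[best][2]) - 1] += 1
        else:
            missed[g.class_label.label] = missed.get(g.class_label.label, 0) + 1
    for di in range(len(result.refined)):
        if det_matched[di]:
            continue
        # false positive over background / normal cells -> NILM row
        cm1[nilm, int(result.detections[di].class_label) - 1] += 1
        cm2[nilm, int(result.refined[di][2]) - 1] += 1
    if not gt_boxes and not result.refined:
        cm1[nilm, nilm] += 1
        cm2[nilm, nilm] += 1


def run_batch(
    manifest: str | Path | pd.DataFrame,
    detector: DetectorBackend,
    classifier: ClassifierBackend,
    root: str | Path | None = None,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    crop_margin: float = DEFAULT_CROP_MARGIN,
    score: bool = True,
) -> BatchResult:
    """Run the two-step pipeline over a manifest of images.

    ``manifest`` is a CSV path or DataFrame with a ``path`` column; image
    paths resolve against ``root`` (default: the manifest's directory).
    When ``score`` is true and Darknet sidecars (``<stem>.txt``) exist, the
    per-stage confusion matrices are accumulated; rows lacking a sidecar are
    reported without scoring.  Per-row failures are recorded and the run
    continues; if every row fails, a :class:`DataError` is raised.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        df = pd.read_csv(manifest_path)
        root = Path(root) if root is not None else manifest_path.parent
    else:
        df = manifest
        root = Path(root) if root is not None else Path(".")
    if "path" not in df.columns:
        raise DataError("manifest must have a 'path' column")

    cm1 = np.zeros((NUM_CLASSES, NUM_CLASSES), dtype=np.int64)
    cm2 = np.zeros_like(cm1)
    missed: dict[str, int] = {}
    any_truth = False
    rows = []
    errors: list[str] = []
    n_ok = 0
    for _, rec in df.iterrows():
        img_path = root / rec["path"]
        try:
            img = load_image(img_path)
            result = run_two_step(
                img, detector, classifier, conf_threshold, crop_margin
            )
        except Exception as exc:
            errors.append(f"{rec['path']}: {exc}")
            continue
        n_ok += 1
        ann_path = img_path.with_suffix(".txt")
        if score and ann_path.exists():
            any_truth = True
            _match_and_accumulate(result, read_darknet(ann_path), cm1, cm2, missed)
        if result.refined:
            for box, probs, final in result.refined:
                rows.append(
                    {
                        "image": rec["path"],
                        "cx": box.cx, "cy": box.cy, "w": box.w, "h": box.h,
                        "confidence": box.confidence,
                        "stage1_class": box.class_label.label,
                        **{f"p_{n}": p for n, p in zip(CLASS_NAMES, probs)},
                        "final_class": final.label,
                        "image_call": result.image_call.label,
                    }
                )
        else:
            rows.append(
                {
                    "image": rec["path"],
                    "cx": np.nan, "cy": np.nan, "w": np.nan, "h": np.nan,
                    "confidence": np.nan, "stage1_class": None,
                    **{f"p_{n}": np.nan for n in CLASS_NAMES},
                    "final_class": None,
                    "image_call": result.image_call.label,
                }
            )
    if n_ok == 0 and len(df) > 0:
        raise DataError(f"all {len(df)} manifest rows failed: {errors[:3]} ...")
    return BatchResult(
        results=pd.DataFrame(rows),
        stage1=ConfusionMatrix(cm1) if any_truth else None,
        stage2=ConfusionMatrix(cm2) if any_truth else None,
        missed=missed if any_truth else None,
        errors=tuple(errors),
    )
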