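"""Bounding boxes in normalized Darknet/YOLO convention, IoU, and sidecar I/O.

A box is stored as normalized center/size ``(cx, cy, w, h)`` in [0, 1], the
convention of Darknet annotation files: one box per line,
``<class_id> <cx> <cy> <w> <h>``.  On disk the class id is the 0-based ordinal
index (0 = NILM ... 5 = SCC); NILM boxes never occur in practice because
normal clusters are annotated by absence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .ordinal import Bethesda

__all__ = ["BoundingBox", "iou", "read_darknet", "write_darknet"]


@dataclass(frozen=True)
class BoundingBox:
    """One detected or annotated cell cluster."""

    cx: float
    cy: float
    w: float
    h: float
    class_label: Bethesda | None = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w} h={self.h}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        # must intersect the unit square with positive area
        if (
            self.cx + self.w / 2 <= 0
            or self.cx - self.w / 2 >= 1
            or self.cy + self.h / 2 <= 0
            or self.cy - self.h / 2 >= 1
        ):
            raise ValueError("box lies entirely outside the unit square")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) corners in normalized coordinates."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    def to_pixels(self, width: int, height: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) integer pixel corners, clipped to the frame."""
        x0, y0, x1, y1 = self.corners
        return (
            max(0, int(round(x0 * width))),
            max(0, int(round(y0 * height))),
            min(width, int(round(x1 * width))),
            min(height, int(round(y1 * height))),
        )

    def flipped(self, horizontal: bool = False, vertical: bool = False) -> "BoundingBox":
        return replace(
            self,
            cx=1.0 - self.cx if horizontal else self.cx,
            cy=1.0 - self.cy if vertical else self.cy,
        )

    @classmethod
    def from_pixels(
        cls,
        x0: float,
        y0: float,
        x1: float,
        y1: float,
        width: int,
        height: int,
        class_label: Bethesda | None = None,
        confidence: float = 1.0,
    ) -> "BoundingBox":
        return cls(
            cx=(x0 + x1) / 2 / width,
            cy=(y0 + y1) / 2 / height,
            w=(x1 - x0) / width,
            h=(y1 - y0) / height,
            class_label=class_label,
            confidence=confidence,
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two normalized boxes."""
    ax0, ay0, ax1, ay1 = a.corners
    bx0, by0, bx1, by1 = b.corners
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def read_darknet(path: str | Path) -> list[BoundingBox]:
    """Read a Darknet annotation sidecar; an empty file means no clusters."""
    out: list[BoundingBox] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        cls_id = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:])
        out.append(
            BoundingBox(cx=cx, cy=cy, w=w, h=h, class_label=Bethesda(cls_id + 1))
        )
    return out


def write_darknet(path: str | Path, boxes: list[BoundingBox]) -> None:
    lines = []
    for b in boxes:
        if b.class_label is None:
            raise ValueError("cannot write a box without a class label")
        lines.append(
            f"{b.class_label.value - 1} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
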