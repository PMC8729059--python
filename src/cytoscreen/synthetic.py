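"""Seeded synthetic cytology scenes with six ordinal severity classes.

Real liquid-based cytology images of crowded, overlapping cell clusters are
not redistributable, so this module renders toy scenes with the same
*structure*: clusters of overlapping elliptical cells (pale cytoplasm, dark
nucleus) on a pale noisy background with optional debris.  Severity is encoded
the way a cytologist would read it -- higher Bethesda class means

* a larger nucleus-to-cytoplasm area ratio (0.15 at NILM up to 0.75 at SCC,
  linear in class index),
* more variable nuclear size within a cluster, and
* stronger chromatin speckle (intensity texture inside the nucleus),

all non-decreasing in class index, so a monotone image statistic separates the
classes and ordinal classifiers have a learnable signal.  These are rendering
knobs chosen for desk-scale learnability, not claims about real cytology.

NILM clusters are rendered like any others but produce **no** annotation box:
normal cells are annotated by absence, mirroring how the screening pipeline
calls an image NILM when its detector finds nothing.

Every scene is a pure function of its spec (including the seed): identical
specs give bit-identical images and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import CellImage, save_image
from .boxes import BoundingBox, write_darknet
from .errors import DataError
from .ordinal import NUM_CLASSES, Bethesda

__all__ = [
    "SyntheticSceneSpec",
    "ClusterMasks",
    "SceneGroundTruth",
    "class_ratio",
    "generate_scene",
    "generate_crop",
    "generate_cooccurring_crop",
    "generate_dataset",
    "PlacementError",
]

#: Nucleus-to-cytoplasm area-ratio ladder: 0.15 (NILM) to 0.75 (SCC).
_RATIO_LOW, _RATIO_HIGH = 0.15, 0.75

#: Background and tissue tints (RGB, uint8 scale).
_BACKGROUND = np.array([232, 226, 235], dtype=float)
_CYTOPLASM = np.array([188, 202, 224], dtype=float)
_NUCLEUS = np.array([96, 66, 128], dtype=float)


class PlacementError(DataError):
    """Raised when clusters cannot be placed at the requested crowding."""


def class_ratio(k: Bethesda | int) -> float:
    """Target nucleus/cytoplasm area ratio for a severity class (linear ladder)."""
    k = int(k)
    return _RATIO_LOW + (_RATIO_HIGH - _RATIO_LOW) * (k - 1) / (NUM_CLASSES - 1)


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one generated scene.

    ``crowding`` in [0, 1] packs cluster centres more tightly (more overlap);
    ``background_debris`` in [0, 1] controls the density of small stray
    particles outside the clusters.
    """

    width: int = 128
    height: int = 128
    n_clusters: int = 1
    class_per_cluster: tuple[Bethesda, ...] = (Bethesda.HSIL,)
    crowding: float = 0.5
    background_debris: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        labels = tuple(Bethesda(c) for c in self.class_per_cluster)
        object.__setattr__(self, "class_per_cluster", labels)
        if len(labels) != self.n_clusters:
            raise ValueError(
                f"class_per_cluster has {len(labels)} entries for "
                f"n_clusters={self.n_clusters}"
            )
        if not 0.0 <= self.crowding <= 1.0:
            raise ValueError("crowding must lie in [0, 1]")
        if not 0.0 <= self.background_debris <= 1.0:
            raise ValueError("background_debris must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterMasks:
    """Boolean nucleus and cytoplasm masks of one cluster."""

    nucleus: np.ndarray
    cytoplasm: np.ndarray

    @property
    def area_ratio(self) -> float:
        cyto = int(self.cytoplasm.sum())
        return float(self.nucleus.sum()) / cyto if cyto else 0.0


@dataclass(frozen=True)
class SceneGroundTruth:
    """Boxes (atypical clusters only) plus per-cluster masks (all clusters)."""

    boxes: tuple[BoundingBox, ...]
    masks: tuple[ClusterMasks, ...]


def _ellipse_mask(
    shape: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    h, w = shape
    r0 = max(0, int(cy - max(a, b)) - 1)
    r1 = min(h, int(cy + max(a, b)) + 2)
    c0 = max(0, int(cx - max(a, b)) - 1)
    c1 = min(w, int(cx + max(a, b)) + 2)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _render_cluster(
    canvas: np.ndarray,
    center: tuple[float, float],
    label: Bethesda,
    rng: np.random.Generator,
) -> ClusterMasks:
    """Draw one cluster of overlapping cells; returns its masks."""
    h, w = canvas.shape[:2]
    k = int(label)
    ratio = class_ratio(k)
    # nuclear size spread and chromatin speckle amplitude grow with severity
    size_sigma = 0.05 + 0.04 * (k - 1)
    speckle = 6.0 + 7.0 * (k - 1)
    n_cells = int(rng.integers(3, 8))
    cell_r = rng.uniform(8.0, 11.0)
    spread = cell_r * 1.1
    nuc_mask = np.zeros((h, w), dtype=bool)
    cyto_mask = np.zeros((h, w), dtype=bool)
    cx0, cy0 = center
    for _ in range(n_cells):
        cx = cx0 + rng.normal(0.0, spread)
        cy = cy0 + rng.normal(0.0, spread)
        a = cell_r * rng.uniform(0.85, 1.15)
        b = cell_r * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0.0, np.pi)
        cyto = _ellipse_mask((h, w), cx, cy, a, b, theta)
        tint = _CYTOPLASM + rng.normal(0.0, 6.0, size=3)
        canvas[cyto] = 0.55 * canvas[cyto] + 0.45 * tint
        # nucleus concentric with the cell, area = ratio * cytoplasm area
        r_scale = np.sqrt(ratio) * max(0.2, 1.0 + rng.normal(0.0, size_sigma))
        r_scale = min(r_scale, 0.97)
        nx = cx + rng.normal(0.0, a * 0.08)
        ny = cy + rng.normal(0.0, b * 0.08)
        nuc = _ellipse_mask((h, w), nx, ny, a * r_scale, b * r_scale, theta)
        nuc &= cyto
        shade = _NUCLEUS - 4.0 * (k - 1) + rng.normal(0.0, 4.0, size=3)
        canvas[nuc] = shade
        if nuc.any():
            canvas[nuc] += rng.normal(0.0, speckle, size=(int(nuc.sum()), 3))
        cyto_mask |= cyto
        nuc_mask |= nuc
    return ClusterMasks(nucleus=nuc_mask, cytoplasm=cyto_mask)


def _place_centers(
    spec: SyntheticSceneSpec, rng: np.random.Generator, max_tries: int = 200
) -> list[tuple[float, float]]:
    """Clustered placement: a parent point plus scattered offsets.

    Overlap between clusters is allowed by design; a draw is rejected only
    when the cluster centre escapes the frame margin entirely.
    """
    h, w = spec.height, spec.width
    margin = 14.0
    if spec.n_clusters == 0:
        return []
    if w - margin <= margin or h - margin <= margin:
        raise PlacementError(
            f"frame {w}x{h} too small to place any cluster "
            f"(needs > {2 * margin:g} px per side; {spec!r})"
        )
    parent = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
    scatter = (0.45 - 0.3 * spec.crowding) * min(h, w)
    centers: list[tuple[float, float]] = []
    for _ in range(spec.n_clusters):
        for _ in range(max_tries):
            cx = parent[0] + rng.normal(0.0, scatter)
            cy = parent[1] + rng.normal(0.0, scatter)
            if margin <= cx <= w - margin and margin <= cy <= h - margin:
                centers.append((cx, cy))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_clusters} clusters at "
                f"crowding={spec.crowding} in a {w}x{h} frame ({spec!r})"
            )
    return centers


def generate_scene(spec: SyntheticSceneSpec) -> tuple[CellImage, SceneGroundTruth]:
    """Render one scene; bit-identical for identical specs.

    Each atypical cluster yields exactly one annotation box -- the bounding
    rectangle of its cytoplasm mask; NILM clusters yield none.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.tile(_BACKGROUND, (h, w, 1))
    canvas += rng.normal(0.0, 3.0, size=(h, w, 3))
    n_debris = int(round(spec.background_debris * h * w / 550.0))
    for _ in range(n_debris):
        dx, dy = rng.uniform(0, w), rng.uniform(0, h)
        r = rng.uniform(0.8, 2.2)
        dmask = _ellipse_mask((h, w), dx, dy, r, r, 0.0)
        canvas[dmask] = rng.uniform(120, 200) + rng.normal(0.0, 5.0, size=3)

    centers = _place_centers(spec, rng)
    boxes: list[BoundingBox] = []
    masks: list[ClusterMasks] = []
    for center, label in zip(centers, spec.class_per_cluster):
        m = _render_cluster(canvas, center, label, rng)
        masks.append(m)
        if label is Bethesda.NILM or not m.cytoplasm.any():
            continue
        rows, cols = np.nonzero(m.cytoplasm)
        boxes.append(
            BoundingBox.from_pixels(
                cols.min(), rows.min(), cols.max() + 1, rows.max() + 1,
                width=w, height=h, class_label=label,
            )
        )
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    img = CellImage(pixels=pixels, id=f"scene_{spec.seed}", class_label=None)
    return img, SceneGroundTruth(boxes=tuple(boxes), masks=tuple(masks))


def generate_crop(
    label: Bethesda | int, seed: int, size: int = 64, crowding: float = 0.7
) -> CellImage:
    """Single-cluster crop of the given class, for classifier training."""
    spec = SyntheticSceneSpec(
        width=size,
        height=size,
        n_clusters=1,
        class_per_cluster=(Bethesda(label),),
        crowding=crowding,
        background_debris=0.1,
        seed=seed,
    )
    img, _ = generate_scene(spec)
    return CellImage(pixels=img.pixels, id=img.id, class_label=Bethesda(label))


def generate_cooccurring_crop(
    label: Bethesda | int,
    seed: int,
    size: int = 96,
    margin: float = 0.15,
) -> CellImage:
    """Annotation-box crop of a target cluster in a crowded mixed field.

    The scene holds the target cluster plus one or two neighbours whose
    severity differs by one class -- neighbouring grades co-occur on real
    slides because progression is continuous -- and the crop is the target
    cluster's bounding rectangle plus a margin, so neighbouring material
    bleeds into the crop.  This is the realistic (harder) crop regime for
    classifier studies: the crop's content mixes adjacent severities, which
    is precisely the ambiguity ordinal label smoothing is meant to absorb.
    """
    label = Bethesda(label)
    rng = np.random.default_rng(seed)
    n_extra = int(rng.integers(1, 3))
    neigh = [
        Bethesda(int(np.clip(int(label) + rng.choice([-1, 1]), 1, NUM_CLASSES)))
        for _ in range(n_extra)
    ]
    spec = SyntheticSceneSpec(
        width=size,
        height=size,
        n_clusters=1 + n_extra,
        class_per_cluster=(label, *neigh),
        crowding=0.9,
        background_debris=0.15,
        seed=int(rng.integers(2**31 - 1)),
    )
    img, truth = generate_scene(spec)
    mask = truth.masks[0].cytoplasm
    if not mask.any():
        return CellImage(pixels=img.pixels, id=img.id, class_label=label)
    rows, cols = np.nonzero(mask)
    mh = int(round((rows.max() - rows.min()) * margin))
    mw = int(round((cols.max() - cols.min()) * margin))
    r0, r1 = max(0, rows.min() - mh), min(size, rows.max() + 1 + mh)
    c0, c1 = max(0, cols.min() - mw), min(size, cols.max() + 1 + mw)
    return CellImage(
        pixels=np.ascontiguousarray(img.pixels[r0:r1, c0:c1]),
        id=f"{img.id}_crop",
        class_label=label,
    )


def _split_of(index: int, n: int) -> str:
    """70/15/15 train/validation/test split, per class, deterministic."""
    n_train = int(round(n * 0.70))
    n_val = int(round(n * 0.15))
    if index < n_train:
        return "train"
    if index < n_train + n_val:
        return "validation"
    return "test"


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    seed: int = 0,
    spec_template: SyntheticSceneSpec | None = None,
    classes: tuple[Bethesda, ...] = tuple(Bethesda),
) -> pd.DataFrame:
    """Write a balanced, annotated scene dataset with a 70/15/15 split manifest.

    Each scene contains 1-3 clusters of a single severity class.  Outputs one
    PNG and one Darknet ``.txt`` per scene plus ``manifest.csv`` with columns
    (path, split, classes); NILM annotation files are empty.  Returns the
    manifest.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc
    base = spec_template or SyntheticSceneSpec()
    records = []
    for ci, label in enumerate(classes):
        for j in range(n_per_class):
            scene_seed = int(
                np.random.default_rng([seed, ci, j]).integers(0, 2**31 - 1)
            )
            n_clusters = 1 + int(np.random.default_rng([seed, ci, j, 7]).integers(0, 3))
            spec = SyntheticSceneSpec(
                width=base.width,
                height=base.height,
                n_clusters=n_clusters,
                class_per_cluster=(label,) * n_clusters,
                crowding=base.crowding,
                background_debris=base.background_debris,
                seed=scene_seed,
            )
            img, truth = generate_scene(spec)
            stem = f"{label.label.replace('-', '')}_{j:04d}"
            save_image(
                CellImage(pixels=img.pixels, id=stem), out_dir / f"{stem}.png"
            )
            write_darknet(out_dir / f"{stem}.txt", list(truth.boxes))
            records.append(
                {
                    "path": f"{stem}.png",
                    "split": _split_of(j, n_per_class),
                    "classes": label.label,
                }
            )
    manifest = pd.DataFrame(records, columns=["path", "split", "classes"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
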