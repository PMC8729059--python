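"""Offline 36x oversampling and online scale/erase augmentation.

Microscopy training sets for cytology are small (a few hundred annotated cell
clusters per class), so the training images are oversampled: a bank of nine
photometric filters -- emulating varied light exposure, staining and focus
across capture sessions -- is crossed with the four flip states {identity,
horizontal, vertical, both}, expanding every image into exactly 9 x 4 = 36
augmented variants.  The unmodified original stays in the base set and is not
re-emitted among the 36.

Two further augmentations are applied online (per training iteration, with an
RNG) to classifier training crops only:

* **scale augmentation** -- enlarge by a random factor, then crop a random
  window of the original size;
* **random erasing** -- overwrite one random rectangle with noise, occluding
  part of the cluster.

Photometric filters and flips are deterministic; flips also remap bounding-box
annotations (photometric filters leave them untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import transform as sktransform

from .boxes import BoundingBox, read_darknet, write_darknet
from .errors import ConfigError, DataError
from .ordinal import Bethesda

__all__ = [
    "CellImage",
    "FilterSpec",
    "AugmentationPlan",
    "ORIENTATIONS",
    "default_filter_bank",
    "apply_filter",
    "flip",
    "flip_boxes",
    "expand_dataset",
    "expand_directory",
    "scale_augment",
    "random_erase",
    "load_image",
    "save_image",
]

#: The four flip states crossed with the filter bank.
ORIENTATIONS = ("identity", "horizontal", "vertical", "both")


@dataclass(frozen=True)
class CellImage:
    """An RGB cell-cluster image with an identifier and optional class label."""

    pixels: np.ndarray
    id: str
    class_label: Bethesda | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected an H x W x 3 image, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FilterSpec:
    """A named photometric filter with scalar parameters."""

    name: str
    parameters: dict = field(default_factory=dict)

    @property
    def tag(self) -> str:
        params = "_".join(f"{k}{v:g}" for k, v in sorted(self.parameters.items()))
        return f"{self.name}_{params}" if params else self.name


def default_filter_bank() -> list[FilterSpec]:
    """The default nine-filter photometric bank.

    Brightness and contrast shifts in both directions, gamma below and above
    1, Gaussian blur, unsharp sharpening and a saturation boost -- chosen to
    mimic varying light exposure, stain uptake and focus quality.  Any bank of
    nine :class:`FilterSpec` may be substituted via the augmentation plan.
    """
    return [
        FilterSpec("brightness", {"delta": 30}),
        FilterSpec("brightness", {"delta": -30}),
        FilterSpec("contrast", {"factor": 1.3}),
        FilterSpec("contrast", {"factor": 0.7}),
        FilterSpec("gamma", {"gamma": 0.7}),
        FilterSpec("gamma", {"gamma": 1.5}),
        FilterSpec("gaussian_blur", {"sigma": 1.5}),
        FilterSpec("unsharp", {"radius": 2.0, "amount": 1.0}),
        FilterSpec("saturation", {"factor": 1.5}),
    ]


def _as_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def _brightness(px: np.ndarray, delta: float) -> np.ndarray:
    return _as_uint8(px.astype(np.int32) + int(delta))


def _contrast(px: np.ndarray, factor: float) -> np.ndarray:
    return _as_uint8((px.astype(float) - 128.0) * factor + 128.0)


def _gamma(px: np.ndarray, gamma: float) -> np.ndarray:
    return _as_uint8(255.0 * np.power(px.astype(float) / 255.0, gamma))


def _gaussian_blur(px: np.ndarray, sigma: float) -> np.ndarray:
    out = skfilters.gaussian(
        px.astype(float) / 255.0, sigma=sigma, channel_axis=-1, preserve_range=True
    )
    return _as_uint8(out * 255.0)


def _unsharp(px: np.ndarray, radius: float, amount: float) -> np.ndarray:
    # classic unsharp masking: sharpened = img + amount * (img - blurred)
    img = px.astype(float)
    blurred = skfilters.gaussian(
        img, sigma=radius, channel_axis=-1, preserve_range=True
    )
    return _as_uint8(img + amount * (img - blurred))


def _saturation(px: np.ndarray, factor: float) -> np.ndarray:
    hsv = skcolor.rgb2hsv(px.astype(float) / 255.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * factor, 0.0, 1.0)
    return _as_uint8(skcolor.hsv2rgb(hsv) * 255.0)


_FILTER_FUNCS = {
    "brightness": _brightness,
    "contrast": _contrast,
    "gamma": _gamma,
    "gaussian_blur": _gaussian_blur,
    "unsharp": _unsharp,
    "saturation": _saturation,
}


def apply_filter(img: CellImage, f: FilterSpec) -> CellImage:
    """Apply one photometric filter; deterministic and dimension-preserving."""
    try:
        func = _FILTER_FUNCS[f.name]
    except KeyError:
        raise ConfigError(
            f"unknown filter {f.name!r}; known: {sorted(_FILTER_FUNCS)}"
        ) from None
    out = func(img.pixels, **f.parameters)
    return replace(img, pixels=out, id=f"{img.id}__{f.tag}")


def flip(img: CellImage, state: str) -> CellImage:
    """Flip an image; ``state`` is one of identity/horizontal/vertical/both."""
    if state not in ORIENTATIONS:
        raise ConfigError(f"unknown orientation {state!r}; known: {ORIENTATIONS}")
    px = img.pixels
    if state in ("horizontal", "both"):
        px = px[:, ::-1]
    if state in ("vertical", "both"):
        px = px[::-1]
    return replace(img, pixels=np.ascontiguousarray(px), id=f"{img.id}__{state}")


def flip_boxes(boxes: list[BoundingBox], state: str) -> list[BoundingBox]:
    """Remap normalized box coordinates under a flip state."""
    if state not in ORIENTATIONS:
        raise ConfigError(f"unknown orientation {state!r}; known: {ORIENTATIONS}")
    horizontal = state in ("horizontal", "both")
    vertical = state in ("vertical", "both")
    return [b.flipped(horizontal=horizontal, vertical=vertical) for b in boxes]


@dataclass(frozen=True)
class AugmentationPlan:
    """Full oversampling plan: 9 filters x 4 orientations, plus online knobs.

    ``scale_range`` multipliers must satisfy ``1 <= low <= high`` so the
    enlarged image always contains an original-size crop.  ``erase_prob`` and
    the erase area/aspect ranges follow the canonical random-erasing defaults.
    """

    filters: tuple[FilterSpec, ...] = field(
        default_factory=lambda: tuple(default_filter_bank())
    )
    orientations: tuple[str, ...] = ORIENTATIONS
    scale_range: tuple[float, float] = (1.0, 1.25)
    erase_prob: float = 0.5
    erase_area: tuple[float, float] = (0.02, 0.4)
    erase_aspect: tuple[float, float] = (0.3, 3.3)

    def __post_init__(self) -> None:
        if len(self.filters) != 9:
            raise ConfigError(f"plan requires exactly 9 filters, got {len(self.filters)}")
        if tuple(self.orientations) != ORIENTATIONS:
            raise ConfigError(f"orientations must be {ORIENTATIONS}")
        low, high = self.scale_range
        if not 1.0 <= low <= high:
            raise ConfigError(f"scale_range must satisfy 1 <= low <= high, got {self.scale_range}")
        a0, a1 = self.erase_area
        if not 0.0 < a0 <= a1 < 1.0:
            raise ConfigError(f"erase area fractions must lie in (0, 1), got {self.erase_area}")

    @property
    def expansion_factor(self) -> int:
        return len(self.filters) * len(self.orientations)


def expand_dataset(
    images: list[CellImage], plan: AugmentationPlan | None = None
) -> list[CellImage]:
    """Offline 36x expansion: every image through 9 filters x 4 orientations.

    Output ids carry provenance ``<source>__<filter>__<orientation>``; the
    unmodified originals are not duplicated into the output.
    """
    if plan is None:
        plan = AugmentationPlan()
    out: list[CellImage] = []
    for img in images:
        for f in plan.filters:
            filtered = apply_filter(img, f)
            for state in plan.orientations:
                out.append(flip(filtered, state))
    return out


def scale_augment(
    img: CellImage,
    scale_range: tuple[float, float] = (1.0, 1.25),
    rng: np.random.Generator | int | None = None,
) -> CellImage:
    """Randomly enlarge, then crop back a window of the original size.

    Deterministic given the RNG state/seed; output dimensions always equal the
    input's.
    """
    low, high = scale_range
    if low < 1.0:
        raise ConfigError(f"scale_range low must be >= 1, got {low}")
    rng = np.random.default_rng(rng)
    h, w = img.pixels.shape[:2]
    s = rng.uniform(low, high)
    nh, nw = int(round(h * s)), int(round(w * s))
    if (nh, nw) == (h, w):
        return replace(img, pixels=img.pixels.copy())
    big = sktransform.resize(
        img.pixels.astype(float), (nh, nw), order=1, anti_aliasing=False
    )
    r0 = int(rng.integers(0, nh - h + 1))
    c0 = int(rng.integers(0, nw - w + 1))
    crop = big[r0 : r0 + h, c0 : c0 + w]
    return replace(img, pixels=_as_uint8(crop))


def random_erase(
    img: CellImage,
    erase_prob: float = 0.5,
    area: tuple[float, float] = (0.02, 0.4),
    aspect: tuple[float, float] = (0.3, 3.3),
    rng: np.random.Generator | int | None = None,
    max_tries: int = 100,
) -> CellImage:
    """Overwrite one random rectangle with noise; identity with prob 1-p.

    Pixels outside the rectangle are bit-identical to the input.  If no
    feasible rectangle is found after ``max_tries`` draws, the input is
    returned unchanged.
    """
    if not 0.0 < area[0] <= area[1] < 1.0:
        raise ConfigError(f"erase area fractions must lie in (0, 1), got {area}")
    rng = np.random.default_rng(rng)
    if erase_prob <= 0 or rng.uniform() >= erase_prob:
        return replace(img, pixels=img.pixels.copy())
    h, w = img.pixels.shape[:2]
    for _ in range(max_tries):
        frac = rng.uniform(*area)
        ar = rng.uniform(*aspect)
        eh = int(round(np.sqrt(frac * h * w * ar)))
        ew = int(round(np.sqrt(frac * h * w / ar)))
        if not (1 <= eh <= h and 1 <= ew <= w):
            continue
        r0 = int(rng.integers(0, h - eh + 1))
        c0 = int(rng.integers(0, w - ew + 1))
        out = img.pixels.copy()
        out[r0 : r0 + eh, c0 : c0 + ew] = rng.integers(
            0, 256, size=(eh, ew, 3), dtype=np.uint8
        )
        return replace(img, pixels=out)
    return replace(img, pixels=img.pixels.copy())


def load_image(path: str | Path, class_label: Bethesda | None = None) -> CellImage:
    """Load a PNG/TIFF/JPEG image as a :class:`CellImage`."""
    path = Path(path)
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return CellImage(pixels=px, id=path.stem, class_label=class_label)


def save_image(img: CellImage, path: str | Path) -> None:
    Image.fromarray(img.pixels).save(path)


_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def expand_directory(
    in_dir: str | Path, out_dir: str | Path, plan: AugmentationPlan | None = None
) -> pd.DataFrame:
    """Expand every image in ``in_dir`` 36x into ``out_dir``.

    Darknet annotation sidecars (``<stem>.txt``) are carried over with box
    coordinates remapped under flips.  Returns the provenance manifest, also
    written to ``out_dir/manifest.csv`` with columns
    (source_id, filter, orientation, output_path).
    """
    if plan is None:
        plan = AugmentationPlan()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    paths = sorted(p for p in in_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths and not in_dir.exists():
        raise DataError(f"input directory {in_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for path in paths:
        img = load_image(path)
        ann_path = path.with_suffix(".txt")
        boxes = read_darknet(ann_path) if ann_path.exists() else None
        for f in plan.filters:
            filtered = apply_filter(img, f)
            for state in plan.orientations:
                aug = flip(filtered, state)
                out_path = out_dir / f"{aug.id}.png"
                save_image(aug, out_path)
                if boxes is not None:
                    write_darknet(out_path.with_suffix(".txt"), flip_boxes(boxes, state))
                records.append(
                    {
                        "source_id": img.id,
                        "filter": f.tag,
                        "orientation": state,
                        "output_path": str(out_path),
                    }
                )
    manifest = pd.DataFrame(
        records, columns=["source_id", "filter", "orientation", "output_path"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
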