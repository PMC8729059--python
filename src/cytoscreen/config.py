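"""Validated run configuration and seeded randomness fan-out.

A run is configured from a YAML key-value file; unknown keys are rejected so
typos fail loudly before any work starts.  All randomness flows from a single
master seed: each consumer draws a named substream via :func:`substream`, so
adding a new randomized component never perturbs the streams of existing
ones.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError
from .ordinal import CLASS_NAMES

__all__ = ["RunConfig", "load_config", "save_config", "substream"]


class RunConfig(BaseModel):
    """Schema-validated configuration shared by all subcommands."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    class_order: tuple[str, ...] = CLASS_NAMES
    #: label-smoothing base; 1 = flat, larger = sharper, None would be one-hot
    smoothing_n: int = Field(default=2, ge=1)
    #: renormalize smoothed targets to sum to 1
    normalized: bool = False
    #: detector confidence threshold at inference
    conf_threshold: float = Field(default=0.25, ge=0.0, le=1.0)
    #: crop margin around detector boxes fed to the classifier
    crop_margin: float = Field(default=0.10, ge=0.0, le=1.0)
    #: scale-augmentation multiplier range (low >= 1)
    scale_range: tuple[float, float] = (1.0, 1.25)
    #: random-erasing probability and area/aspect ranges
    erase_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    erase_area: tuple[float, float] = (0.02, 0.4)
    erase_aspect: tuple[float, float] = (0.3, 3.3)
    #: master seed; every random substream derives from it
    seed: int = Field(default=0, ge=0)
    #: optional input/output paths, free-form
    paths: dict[str, str] = Field(default_factory=dict)

    @field_validator("class_order")
    @classmethod
    def _check_class_order(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if tuple(v) != CLASS_NAMES:
            raise ValueError(
                f"class_order must be the Bethesda severity order {CLASS_NAMES}"
            )
        return tuple(v)

    @field_validator("scale_range")
    @classmethod
    def _check_scale(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not 1.0 <= v[0] <= v[1]:
            raise ValueError(f"scale_range must satisfy 1 <= low <= high, got {v}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; missing keys take documented defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        bad = ", ".join(
            "->".join(str(p) for p in e["loc"]) or "(root)" for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: offending keys: {bad}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = cfg.model_dump()
    data["class_order"] = list(data["class_order"])
    for key in ("scale_range", "erase_area", "erase_aspect"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )
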