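"""Bethesda ordinal class system, label smoothing, and the smoothed cross-entropy loss.

The Bethesda system grades squamous cervical cytology on an ordinal severity
scale, NILM < ASC-US < LSIL < ASC-H < HSIL < SCC.  Because disease progression
is continuous, cell clusters near a class boundary are visually similar to
their ordinal neighbours, so a one-hot training target ("the truth is exactly
LSIL") discards information.  The label-smoothing scheme implemented here
replaces the one-hot target for true class ``k`` with geometrically decaying
weights

    y_i = n ** -|k - i|,        i = 1..c,

where ``n >= 1`` is an integer hyperparameter: the true class keeps weight
exactly 1 and weight halves (for n=2) with each step of ordinal distance.  The
cross-entropy loss ``-sum_i y_i log(p_i)`` then rewards probability mass placed
on classes adjacent to the truth, encoding the co-occurrence structure of the
ordinal scale.

By default the smoothed vector is left unnormalized (its sum exceeds 1, the
true-class weight is exactly 1); pass ``normalized=True`` to rescale it to a
probability distribution, which most loss frameworks expect.  Normalization
rescales the loss by a constant per true class and does not change its argmin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NUM_CLASSES",
    "CLASS_NAMES",
    "Bethesda",
    "SmoothLabel",
    "smooth_label",
    "one_hot",
    "cross_entropy",
    "PROB_FLOOR",
]

#: Number of squamous Bethesda classes handled by the system.
NUM_CLASSES = 6

#: Severity order; index in this tuple + 1 is the 1-based ordinal index.
CLASS_NAMES = ("NILM", "ASC-US", "LSIL", "ASC-H", "HSIL", "SCC")

#: Floor applied to probabilities before taking logarithms.
PROB_FLOOR = 1e-12


class Bethesda(enum.IntEnum):
    """Ordinal Bethesda severity class; integer value is the 1-based index."""

    NILM = 1
    ASC_US = 2
    LSIL = 3
    ASC_H = 4
    HSIL = 5
    SCC = 6

    @property
    def label(self) -> str:
        """Display name with the conventional hyphenation (e.g. ``ASC-US``)."""
        return CLASS_NAMES[self.value - 1]

    @classmethod
    def from_label(cls, name: str) -> "Bethesda":
        key = name.strip().upper().replace("-", "_").replace(" ", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown Bethesda class {name!r}; expected one of {CLASS_NAMES}"
            ) from None


def _check_k(k: int, c: int) -> int:
    k = int(k)
    if not 1 <= k <= c:
        raise IndexError(f"class index k={k} out of range [1, {c}]")
    return k


@dataclass(frozen=True)
class SmoothLabel:
    """A (possibly smoothed) training target over the ordinal classes.

    ``weights`` is indexed 0-based; the true class ``k`` is 1-based, matching
    the ordinal indices used throughout.
    """

    weights: np.ndarray
    k: int
    n: float = field(default=float("inf"))
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or np.any(w < 0):
            raise ValueError("weights must be a 1-D non-negative vector")

    def __len__(self) -> int:
        return self.weights.size

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.weights, dtype=dtype)


def smooth_label(
    k: int, c: int = NUM_CLASSES, n: int = 2, normalized: bool = False
) -> SmoothLabel:
    """Smoothed target for true class ``k`` with weights ``n ** -|k - i|``.

    Parameters
    ----------
    k : int
        1-based index of the correct class.
    c : int
        Number of classes.
    n : int
        Smoothing base, >= 1.  ``n = 1`` gives a flat target; larger ``n``
        concentrates weight on the true class (``n -> inf`` recovers one-hot).
    normalized : bool
        If True, rescale the vector to sum to 1 (shape preserved).
    """
    k = _check_k(k, c)
    if n < 1:
        raise ValueError(f"smoothing base n must be >= 1, got {n}")
    i = np.arange(1, c + 1)
    w = np.power(float(n), -np.abs(k - i).astype(float))
    if normalized:
        w = w / w.sum()
    return SmoothLabel(weights=w, k=k, n=float(n), normalized=normalized)


def one_hot(k: int, c: int = NUM_CLASSES) -> SmoothLabel:
    """One-hot target: weight 1 at the true class, 0 elsewhere.

    Equals the ``n -> inf`` limit of :func:`smooth_label`.
    """
    k = _check_k(k, c)
    w = np.zeros(c)
    w[k - 1] = 1.0
    return SmoothLabel(weights=w, k=k, n=float("inf"), normalized=True)


def cross_entropy(label: SmoothLabel | np.ndarray, probs: np.ndarray) -> float:
    """Cross-entropy ``-sum_i y_i log(p_i)`` between a target and a prediction.

    With a one-hot target this reduces to ``-log(p_k)``; with a smoothed
    target every term contributes, weighted by ordinal proximity to the truth.
    Natural logarithm; probabilities must be strictly positive and are floored
    at :data:`PROB_FLOOR` before the log.
    """
    y = np.asarray(label, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {p.shape}")
    if np.any(p <= 0):
        raise ValueError("prediction probabilities must be strictly positive")
    return float(-(y * np.log(np.maximum(p, PROB_FLOOR))).sum())
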