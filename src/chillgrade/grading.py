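"""Leaf/injury segmentation, injury-area ratio and 4-level chilling-injury grade.

Chilling injury on chlorophyll-fluorescence pseudo-color imagery is graded by
the fraction of leaf pixels that belong to injured tissue,

    Lk = A1 / A = N1 / N,

where ``N1`` is the injured-pixel count and ``N`` the total leaf-pixel count.
The ratio maps onto four severity levels:

    ========  =============  ==================
    label     level          Lk band
    ========  =============  ==================
    A         1 (sound)      [0, 0.05)
    B         2 (slight)     [0.05, 0.15)
    C         3 (moderate)   [0.15, 0.30)
    D         4 (severe)     [0.30, 1]
    ========  =============  ==================

Band edges are half-open, closed on the left, so the mapping is total and
deterministic.  Segmentation is plain HSV thresholding: on the pseudo-color
convention used here, healthy leaf tissue is red, injured tissue yellow-green
and the background black, so brightness separates leaf from background and hue
separates injury from healthy tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from skimage import color as skcolor
from skimage import measure

__all__ = [
    "GRADE_LABELS",
    "GRADE_EDGES",
    "Grade",
    "InjuryMeasurement",
    "SegmentationConfig",
    "segment_leaf",
    "segment_injury",
    "injury_ratio",
    "grade",
    "grade_image",
]

GRADE_LABELS = ("A", "B", "C", "D")
#: left edges of the B, C, D bands (A starts at 0)
GRADE_EDGES = (0.05, 0.15, 0.30)


@dataclass(frozen=True)
class Grade:
    """Severity grade: label in {A,B,C,D} paired with level 1-4."""

    label: str
    level: int

    def __post_init__(self):
        if (self.label, self.level) not in zip(GRADE_LABELS, (1, 2, 3, 4)):
            raise ValueError(f"inconsistent grade {self.label!r}/{self.level}")


@dataclass(frozen=True)
class InjuryMeasurement:
    """Injured-pixel count N1, leaf-pixel count N and their ratio Lk."""

    n_injury: int
    n_leaf: int
    lk: float

    def __post_init__(self):
        if self.n_injury > self.n_leaf:
            raise ValueError("injured pixels exceed leaf pixels")


@dataclass(frozen=True)
class SegmentationConfig:
    """HSV thresholds for the pseudo-color convention.

    ``v_background`` separates leaf from background on brightness (V);
    ``injury_hue`` is the closed hue interval (H in [0,1]) treated as injured
    yellow-green tissue; components smaller than ``min_component_frac`` of the
    image area are dropped as noise.  Defaults are tuned to the synthetic
    convention (red leaf / yellow-green injury / black background); re-tune for
    real PAM imagery.
    """

    v_background: float = 0.12
    injury_hue: tuple[float, float] = (0.12, 0.40)
    min_component_frac: float = 0.001


def segment_leaf(image, config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean leaf mask: bright (non-background) pixels, small specks removed.

    Raises ``ValueError("no leaf found")`` on an all-background image.
    """
    config = config or SegmentationConfig()
    rgb = np.asarray(image.rgb, dtype=float) / 255.0
    v = rgb.max(axis=2)  # HSV value channel
    mask = v > config.v_background
    if mask.any():
        labels = measure.label(mask, connectivity=2)
        min_px = max(1, int(config.min_component_frac * mask.size))
        keep = np.flatnonzero(np.bincount(labels.ravel())[1:] >= min_px) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise ValueError("no leaf found")
    return mask


def segment_injury(image, leaf_mask: np.ndarray,
                   config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean injury mask: leaf pixels whose hue falls in the yellow-green band."""
    config = config or SegmentationConfig()
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    hsv = skcolor.rgb2hsv(np.asarray(image.rgb, dtype=float) / 255.0)
    lo, hi = config.injury_hue
    hue = hsv[..., 0]
    return leaf_mask & (hue >= lo) & (hue <= hi)


def injury_ratio(injury_mask: np.ndarray, leaf_mask: np.ndarray) -> InjuryMeasurement:
    """Exact injured-area ratio Lk = N1 / N from the two masks."""
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    if (injury_mask & ~leaf_mask).any():
        raise ValueError("injury mask extends outside the leaf mask")
    n1 = int(np.count_nonzero(injury_mask))
    n = int(np.count_nonzero(leaf_mask))
    return InjuryMeasurement(n_injury=n1, n_leaf=n, lk=float(Fraction(n1, n)))


def grade(lk: float) -> Grade:
    """Map an injury ratio to its grade (half-open bands, closed on the left)."""
    if not 0.0 <= lk <= 1.0:
        raise ValueError(f"lk must lie in [0,1], got {lk}")
    level = 1 + int(np.searchsorted(GRADE_EDGES, lk, side="right"))
    return Grade(label=GRADE_LABELS[level - 1], level=level)


def grade_image(image, config: SegmentationConfig | None = None):
    """Run the full segment -> ratio -> grade chain on one image.

    Returns ``(InjuryMeasurement, Grade)``.
    """
    leaf = segment_leaf(image, config)
    injury = segment_injury(image, leaf, config)
    meas = injury_ratio(injury, leaf)
    return meas, grade(meas.lk)
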