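"""Seeded synthetic chlorophyll-fluorescence leaf images with ground truth.

Pulse-amplitude-modulated (PAM) fluorescence imagers render the fluorescence
yield of a leaf as a pseudo-color image in which healthy tissue appears red,
chilling-injured tissue yellow-green and the non-leaf background black, next to
the raw fluorescence grayscale image.  This module emulates that qualitative
convention with full ground truth (leaf mask, injury mask, exact injured-area
ratio and grade), so the grading/feature/classifier chain can be exercised and
validated without the original instrument imagery.

What is emulated: the three disjoint value bands (red leaf / yellow-green
injury / near-black background), depressed fluorescence yield inside injured
tissue, blob-like injury geometry, and controllable injured-area fraction.
What is not: PAM radiometry, the instrument's exact pseudo-color lookup table,
leaf venation or specular structure.

Hue conventions (H in [0,1]): healthy red H in [0.95,1]∪[0,0.06]; injury
yellow-green H in [0.16,0.33]; background V < 0.08.  Hue jitter is clipped to
its band, so the bands stay disjoint for any noise level; the grayscale noise
cap for which segmentation-accuracy guarantees are tested is noise_sd <= 25.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor
from skimage import draw

from .grading import GRADE_EDGES, GRADE_LABELS, Grade, grade

__all__ = [
    "FluorescenceImage",
    "LeafTruth",
    "SyntheticDataset",
    "make_leaf_image",
    "make_dataset",
    "make_feature_table",
    "write_dataset",
    "TABLE8_TRAIN_COUNTS",
    "TABLE8_TEST_COUNTS",
]

#: default per-class image counts of the study design (train / test)
TABLE8_TRAIN_COUNTS = (42, 46, 46, 42)
TABLE8_TEST_COUNTS = (10, 12, 12, 10)

# gray-level means of the simulated fluorescence-yield field
_GRAY_HEALTHY = 180.0
_GRAY_INJURED = 90.0

_HUE_HEALTHY = (0.95, 1.06)   # wraps through 0 -> [0.95,1]∪[0,0.06]
_HUE_INJURY = (0.16, 0.33)

# realized-ratio tolerance of the blob accretion loop; tighter than the
# documented ±0.02 contract so per-class sampling bands can stay clear of the
# grade edges
_LK_TOL = 0.005


@dataclass(frozen=True)
class LeafTruth:
    """Ground truth attached to a synthetic image."""

    leaf_mask: np.ndarray
    injury_mask: np.ndarray
    lk_true: float
    grade_true: Grade


@dataclass(frozen=True)
class FluorescenceImage:
    """Paired pseudo-color RGB and fluorescence grayscale rasters."""

    rgb: np.ndarray          # H×W×3 uint8
    gray: np.ndarray         # H×W uint8
    id: str
    truth: LeafTruth | None = None

    def __post_init__(self):
        if self.rgb.shape[:2] != self.gray.shape:
            raise ValueError("rgb and gray rasters disagree in shape")
        if min(self.gray.shape) < 16:
            raise ValueError("image must be at least 16x16")


@dataclass
class SyntheticDataset:
    """Labelled train/test image collections with their grade labels."""

    train: list[FluorescenceImage] = field(default_factory=list)
    test: list[FluorescenceImage] = field(default_factory=list)

    @property
    def train_labels(self) -> list[str]:
        return [im.truth.grade_true.label for im in self.train]

    @property
    def test_labels(self) -> list[str]:
        return [im.truth.grade_true.label for im in self.test]


def _leaf_mask(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Union of 1-3 random ellipses, kept away from the borders."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        cy = rng.uniform(0.35 * h, 0.65 * h)
        cx = rng.uniform(0.35 * w, 0.65 * w)
        ry = rng.uniform(0.18 * h, 0.30 * h)
        rx = rng.uniform(0.18 * w, 0.30 * w)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
        mask[rr, cc] = True
    return mask


def _accrete_injury(rng: np.random.Generator, leaf: np.ndarray,
                    target_lk: float, max_iter: int = 20000) -> np.ndarray:
    """Grow random disks inside the leaf until |lk - target| <= _LK_TOL.

    Disks that would overshoot are shrunk; a single pixel always fits, so each
    accepted step makes progress.
    """
    injury = np.zeros_like(leaf)
    n_leaf = int(leaf.sum())
    if target_lk <= 0:
        return injury
    ys, xs = np.nonzero(leaf)
    shape = leaf.shape
    target_n = target_lk * n_leaf
    n_cur = 0
    for _ in range(max_iter):
        if n_cur >= target_n - _LK_TOL * n_leaf:
            return injury
        remaining = target_n + _LK_TOL * n_leaf - n_cur
        j = rng.integers(len(ys))
        r = rng.uniform(1.5, max(2.0, 0.08 * min(shape)))
        r = min(r, np.sqrt(remaining / np.pi))
        for _shrink in range(8):
            rr, cc = draw.disk((ys[j], xs[j]), max(r, 0.5), shape=shape)
            cand = injury.copy()
            cand[rr, cc] = True
            cand &= leaf
            n_new = int(cand.sum())
            if n_new <= target_n + _LK_TOL * n_leaf:
                injury, n_cur = cand, n_new
                break
            r /= 2.0
    achieved = n_cur / n_leaf
    if abs(achieved - target_lk) <= _LK_TOL:
        return injury
    raise RuntimeError(
        f"could not reach target injury ratio {target_lk:.4f}; achieved {achieved:.4f}")


def make_leaf_image(seed: int, target_lk: float, size: tuple[int, int] = (96, 96),
                    noise_sd: float = 8.0, id: str | None = None) -> FluorescenceImage:
    """Generate one synthetic fluorescence leaf image with ground truth.

    Parameters
    ----------
    seed
        Seeds the image's private RNG; identical seeds give bit-identical rasters.
    target_lk
        Desired injured-area fraction in [0, 0.8]; realized within ±0.02
        (in practice ±0.005).
    size
        (H, W), at least 32×32.
    noise_sd
        Gray-level standard deviation of the fluorescence-yield noise; also
        scales (band-clipped) hue and saturation jitter.
    """
    if not 0.0 <= target_lk <= 0.8:
        raise ValueError("target_lk must lie in [0, 0.8]")
    if min(size) < 32:
        raise ValueError("size must be at least 32x32")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    leaf = _leaf_mask(rng, size)
    injury = _accrete_injury(rng, leaf, target_lk)
    n_leaf = int(leaf.sum())
    lk_true = float(injury.sum()) / n_leaf

    # fluorescence-yield field -> grayscale raster
    yield_field = np.zeros(size, dtype=float)
    yield_field[leaf] = _GRAY_HEALTHY
    yield_field[injury] = _GRAY_INJURED
    noise = rng.normal(0.0, noise_sd, size=size)
    gray = np.clip(np.where(leaf, yield_field + noise, 0.0), 0, 255)
    gray = np.round(gray).astype(np.uint8)

    # pseudo-color raster assembled in HSV
    hue = np.zeros(size, dtype=float)
    jitter = rng.normal(0.0, noise_sd / 500.0, size=size)
    h_lo, h_hi = _HUE_HEALTHY
    hue[leaf] = np.clip(0.995 + jitter[leaf], h_lo, h_hi) % 1.0
    i_lo, i_hi = _HUE_INJURY
    hue[injury] = np.clip(0.245 + jitter[injury], i_lo + 0.003, i_hi - 0.003)
    sat = np.zeros(size, dtype=float)
    sat[leaf] = np.clip(0.88 + rng.normal(0, noise_sd / 400.0, size=size)[leaf], 0.6, 1.0)
    val = np.zeros(size, dtype=float)
    val[leaf] = np.clip(gray[leaf] / 255.0, 0.25, 1.0)
    rgb = skcolor.hsv2rgb(np.stack([hue, sat, val], axis=-1))
    rgb = np.round(rgb * 255.0).astype(np.uint8)

    truth = LeafTruth(leaf_mask=leaf, injury_mask=injury, lk_true=lk_true,
                      grade_true=grade(lk_true))
    return FluorescenceImage(rgb=rgb, gray=gray, id=id or f"syn-{seed}", truth=truth)


def _class_band(level: int) -> tuple[float, float]:
    """Sampling band for target_lk inside one grade, inset from the edges."""
    edges = (0.0,) + GRADE_EDGES + (0.55,)
    inset = _LK_TOL + 0.0075
    lo = max(edges[level - 1] + inset, 0.005)
    hi = edges[level] - inset if level < 4 else edges[level]
    return lo, hi


def make_dataset(seed: int,
                 train_counts: tuple[int, int, int, int] = TABLE8_TRAIN_COUNTS,
                 test_counts: tuple[int, int, int, int] = TABLE8_TEST_COUNTS,
                 size: tuple[int, int] = (96, 96),
                 noise_sd: float = 8.0) -> SyntheticDataset:
    """Generate a stratified train/test image set (defaults: 176 train / 44 test).

    Per class, target ratios are drawn uniformly inside that grade's Lk band,
    inset from the band edges so the realized grade always matches the
    requested class.
    """
    if min(train_counts) < 1 or min(test_counts) < 1:
        raise ValueError("per-class counts must be >= 1")
    rng = np.random.default_rng(seed)
    ds = SyntheticDataset()
    for split, counts, images in (("train", train_counts, ds.train),
                                  ("test", test_counts, ds.test)):
        for level, count in enumerate(counts, start=1):
            lo, hi = _class_band(level)
            for k in range(count):
                target = float(rng.uniform(lo, hi))
                img_seed = int(rng.integers(0, 2**31 - 1))
                img = make_leaf_image(
                    img_seed, target, size=size, noise_sd=noise_sd,
                    id=f"{split}-{GRADE_LABELS[level - 1]}-{k:03d}")
                assert img.truth.grade_true.level == level
                images.append(img)
    return ds


def make_feature_table(seed: int, n_per_class: int, class_separation: float,
                       n_features: int = 9):
    """Fast tabular stand-in for the selected-feature matrix (classifier tests).

    Rows are drawn from four unit-variance Gaussians whose means move
    monotonically with grade level: mean of feature f for level c is
    ``c * class_separation * s_f`` with a fixed sign pattern s_f (some
    features correlate negatively with severity).  ``class_separation=0``
    gives four identical distributions (chance-level problem).

    Returns ``(X, labels)`` with X of shape (4*n_per_class, n_features) and
    labels a list of grade letters.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if class_separation < 0:
        raise ValueError("class_separation must be >= 0")
    rng = np.random.default_rng(seed)
    signs = np.array([1 if f % 3 else -1 for f in range(n_features)], dtype=float)
    rows, labels = [], []
    for level, label in enumerate(GRADE_LABELS, start=1):
        mean = level * class_separation * signs
        rows.append(rng.normal(mean, 1.0, size=(n_per_class, n_features)))
        labels.extend([label] * n_per_class)
    return np.vstack(rows), labels


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write PNG rasters, truth masks and a manifest CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "split", "grade", "lk_true"])
        for split, images in (("train", ds.train), ("test", ds.test)):
            for img in images:
                iio.imwrite(outdir / f"{img.id}_rgb.png", img.rgb)
                iio.imwrite(outdir / f"{img.id}_gray.png", img.gray)
                t = img.truth
                iio.imwrite(outdir / f"{img.id}_leaf.png",
                            (t.leaf_mask * 255).astype(np.uint8))
                iio.imwrite(outdir / f"{img.id}_injury.png",
                            (t.injury_mask * 255).astype(np.uint8))
                writer.writerow([img.id, split, t.grade_true.label, f"{t.lk_true:.6f}"])
    return manifest
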