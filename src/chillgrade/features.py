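"""The 36 image features: color descriptors/ratios, histogram statistics,
gray-gradient co-occurrence (GGCM) and gray-level co-occurrence (GLCM) texture.

A fluorescence image contributes 18 color features (means of R, G, B, H, S, V,
L*, a*, b* over the leaf mask plus nine ratios of those means) and 18 grayscale
features: four histogram moments, six GGCM features and the mean/standard
deviation over four directions of the four classical GLCM features.

Definitions
-----------
Histogram (normalized gray-level histogram ``H(i)`` over leaf pixels):
``E = Σ i·H(i)``; ``σ = sqrt(Σ (i−E)²·H(i))``; ``S = cbrt(Σ (i−E)³·H(i))``;
smoothness ``R = 1 − 1/(1+σ_n²)`` with ``σ_n = σ/255`` so that R stays inside
[0,1) instead of saturating.

GGCM (joint counts ``H(i,j)`` of quantized gray level i = 1..Ng and quantized
Sobel gradient magnitude j = 1..Ns, total ``Htot``, ``P = H/Htot``, gradient
threshold ``T``):

* low-gradient advantage   ``T1 = Σ_i Σ_{j<=T} H(i,j) / Htot``
* high-gradient advantage  ``T2 = Σ_i Σ_{j>T} j²·H(i,j) / Htot``
* gray non-uniformity      ``T3 = Σ_i [Σ_j H(i,j)]² / Htot``
* gradient non-uniformity  ``T4 = Σ_j [Σ_i H(i,j)]² / Htot``
* mean gradient            ``μ = Σ_j j·P_j``   (``P_j = Σ_i P(i,j)``)
* gradient sd              ``∂ = sqrt(Σ_j (j−μ)²·P_j)``

GLCM (normalized symmetric co-occurrence ``Q(i,j)`` at one offset, marginal
means/sds μx, μy, σx, σy):
``ASM = ΣΣ Q²``; ``ENT = −ΣΣ Q·log Q`` (natural log, over Q > 0);
``INE = ΣΣ (i−j)²·Q``; ``COR = (ΣΣ i·j·Q − μxμy)/(σxσy)`` (0 when σxσy = 0).

Co-occurring pairs are counted only when both pixels lie inside the leaf mask:
background is not tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage.feature import graycomatrix

__all__ = [
    "FEATURE_NAMES",
    "SELECTED_FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "GGCMatrix",
    "GLCMatrix",
    "color_features",
    "histogram_features",
    "build_ggcm",
    "ggcm_features",
    "build_glcm",
    "glcm_features",
    "extract_all",
    "feature_table",
]

FEATURE_NAMES = (
    "R", "G", "B", "H", "S", "V", "L", "a", "b",
    "G/R", "G/B", "B/R", "S/H", "V/S", "V/H", "L/a", "L/b", "b/a",
    "hist_mean", "hist_sd", "hist_skew", "hist_smooth",
    "T1_low_grad", "T2_high_grad", "T3_gray_nonunif", "T4_grad_nonunif",
    "grad_mean", "grad_sd",
    "energy_mean", "entropy_mean", "inertia_mean", "corr_mean",
    "energy_sd", "entropy_sd", "inertia_sd", "corr_sd",
)

#: the nine gray-image features that form the very-strong correlation group
SELECTED_FEATURE_NAMES = (
    "hist_mean", "hist_sd", "hist_skew", "hist_smooth",
    "T1_low_grad", "T2_high_grad", "T3_gray_nonunif", "T4_grad_nonunif",
    "grad_mean",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Quantization settings for the texture features.

    ``ng``/``ns`` are the GGCM gray and gradient level counts, ``t`` the GGCM
    low/high gradient threshold (midpoint of the gradient axis by default);
    ``glcm_levels``/``glcm_distance`` control the co-occurrence matrix.
    """

    ng: int = 16
    ns: int = 16
    t: int = 8
    glcm_levels: int = 16
    glcm_distance: int = 1


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named 36-element feature record for one image."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("feature count does not match names")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass(frozen=True)
class GGCMatrix:
    """Gray-gradient co-occurrence counts and normalized probabilities."""

    counts: np.ndarray      # Ng × Ns
    total: int
    p: np.ndarray
    t: int

    def __post_init__(self):
        if not 1 <= self.t < self.counts.shape[1]:
            raise ValueError("gradient threshold must satisfy 1 <= T < Ns")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric co-occurrence matrix for one direction."""

    q: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    angle_deg: float = 0.0


def _signed_guard(y: float, eps: float = 1e-9) -> float:
    """Denominator guard preserving sign: |result| >= eps, sign(0) -> +."""
    if abs(y) >= eps:
        return y
    return eps if y >= 0 else -eps


def color_features(rgb: np.ndarray, leaf_mask: np.ndarray) -> np.ndarray:
    """Nine color-space descriptor means and their nine ratios (18 values).

    Descriptors are per-pixel channel means over the leaf mask: R, G, B on the
    0-255 scale; H, S, V in [0,1]; CIELAB (D65) L in [0,100], a and b signed.
    Ratios are ratios of the descriptor means with a small-denominator guard.
    """
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    rgb01 = np.asarray(rgb, dtype=float) / 255.0
    pix = rgb01[leaf_mask]
    r, g, b = (np.mean(pix[:, c]) * 255.0 for c in range(3))
    hsv = skcolor.rgb2hsv(rgb01)[leaf_mask]
    h, s, v = hsv.mean(axis=0)
    lab = skcolor.rgb2lab(rgb01)[leaf_mask]
    ll, la, lb = lab.mean(axis=0)
    ratios = [
        g / _signed_guard(r), g / _signed_guard(b), b / _signed_guard(r),
        s / _signed_guard(h), v / _signed_guard(s), v / _signed_guard(h),
        ll / _signed_guard(la), ll / _signed_guard(lb), lb / _signed_guard(la),
    ]
    return np.array([r, g, b, h, s, v, ll, la, lb, *ratios], dtype=float)


def histogram_features(gray: np.ndarray, leaf_mask: np.ndarray) -> np.ndarray:
    """Histogram mean, standard deviation, cube-root skew moment and smoothness."""
    if not leaf_mask.any():
        raise ValueError("leaf mask is empty")
    vals = np.asarray(gray)[leaf_mask].astype(np.int64)
    hist = np.bincount(vals, minlength=256).astype(float)
    hist /= hist.sum()
    levels = np.arange(256, dtype=float)
    e = float(np.sum(levels * hist))
    var = float(np.sum((levels - e) ** 2 * hist))
    sd = np.sqrt(var)
    skew = float(np.cbrt(np.sum((levels - e) ** 3 * hist)))
    sd_n = sd / 255.0
    smooth = 1.0 - 1.0 / (1.0 + sd_n**2)
    return np.array([e, sd, skew, smooth], dtype=float)


def _sobel_magnitude(gray: np.ndarray) -> np.ndarray:
    g = np.asarray(gray, dtype=float)
    gx = ndimage.sobel(g, axis=1, mode="reflect")
    gy = ndimage.sobel(g, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _check_mask_support(leaf_mask: np.ndarray) -> None:
    ys, xs = np.nonzero(leaf_mask)
    if len(ys) == 0 or np.ptp(ys) < 2 or np.ptp(xs) < 2:
        raise ValueError("mask smaller than the 3x3 gradient support")


def build_ggcm(gray: np.ndarray, leaf_mask: np.ndarray, ng: int = 16,
               ns: int = 16, t: int = 8) -> GGCMatrix:
    """Joint histogram of quantized gray level and Sobel gradient magnitude.

    Gray is quantized uniformly on [0,255] to levels 1..ng; gradient magnitude
    uniformly on [0, observed max over the mask] to levels 1..ns (all mass in
    level 1 for a constant image).  Only leaf pixels are counted.
    """
    if ng < 2 or ns < 2:
        raise ValueError("ng and ns must be >= 2")
    _check_mask_support(leaf_mask)
    gray = np.asarray(gray)
    glev = 1 + (gray[leaf_mask].astype(int) * ng) // 256        # 1..ng
    gmag = _sobel_magnitude(gray)[leaf_mask]
    gmax = gmag.max()
    if gmax > 0:
        slev = np.minimum(1 + np.floor(gmag / gmax * ns).astype(int), ns)
    else:
        slev = np.ones_like(glev)
    counts = np.zeros((ng, ns), dtype=np.int64)
    np.add.at(counts, (glev - 1, slev - 1), 1)
    total = int(counts.sum())
    return GGCMatrix(counts=counts, total=total, p=counts / total, t=t)


def ggcm_features(m: GGCMatrix) -> np.ndarray:
    """Low/high gradient advantage, gray/gradient non-uniformity, gradient moments."""
    if m.total == 0:
        raise ValueError("empty co-occurrence matrix")
    h = m.counts.astype(float)
    ns = h.shape[1]
    j = np.arange(1, ns + 1, dtype=float)
    t1 = h[:, : m.t].sum() / m.total
    t2 = (j[m.t:] ** 2 * h[:, m.t:]).sum() / m.total
    t3 = (h.sum(axis=1) ** 2).sum() / m.total
    t4 = (h.sum(axis=0) ** 2).sum() / m.total
    pj = m.p.sum(axis=0)
    mu = float(np.sum(j * pj))
    sd = float(np.sqrt(np.sum((j - mu) ** 2 * pj)))
    return np.array([t1, t2, t3, t4, mu, sd], dtype=float)


_GLCM_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)


def build_glcm(gray: np.ndarray, leaf_mask: np.ndarray, levels: int = 16,
               distance: int = 1) -> list[GLCMatrix]:
    """Symmetric masked co-occurrence matrices for 0°, 45°, 90° and 135°.

    Pixels outside the leaf mask are mapped to a sentinel level whose row and
    column are dropped after counting, so only within-mask pairs contribute.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    gray = np.asarray(gray)
    quant = (gray.astype(int) * levels) // 256                  # 0..levels-1
    quant = np.where(leaf_mask, quant, levels).astype(np.uint8)
    angles = [np.deg2rad(a) for a in _GLCM_ANGLES_DEG]
    raw = graycomatrix(quant, distances=[distance], angles=angles,
                       levels=levels + 1, symmetric=True, normed=False)
    out = []
    idx = np.arange(levels, dtype=float)
    for k, ang in enumerate(_GLCM_ANGLES_DEG):
        counts = raw[:levels, :levels, 0, k].astype(float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"no valid pixel pairs at direction {ang:g} degrees")
        q = counts / total
        px, py = q.sum(axis=1), q.sum(axis=0)
        mu_x = float(np.sum(idx * px))
        mu_y = float(np.sum(idx * py))
        sigma_x = float(np.sqrt(np.sum((idx - mu_x) ** 2 * px)))
        sigma_y = float(np.sqrt(np.sum((idx - mu_y) ** 2 * py)))
        out.append(GLCMatrix(q=q, mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x,
                             sigma_y=sigma_y, angle_deg=ang))
    return out


def glcm_features(matrices: list[GLCMatrix]) -> np.ndarray:
    """Energy, entropy, inertia, correlation: mean then population sd over directions."""
    asm, ent, ine, cor = [], [], [], []
    for m in matrices:
        q = m.q
        asm.append(float(np.sum(q**2)))
        pos = q[q > 0]
        ent.append(float(-np.sum(pos * np.log(pos))))
        i, j = np.indices(q.shape)
        ine.append(float(np.sum((i - j) ** 2 * q)))
        denom = m.sigma_x * m.sigma_y
        if denom == 0:
            cor.append(0.0)
        else:
            cor.append(float((np.sum(i * j * q) - m.mu_x * m.mu_y) / denom))
    stats = [np.asarray(x, dtype=float) for x in (asm, ent, ine, cor)]
    means = [s.mean() for s in stats]
    sds = [s.std() for s in stats]
    return np.array(means + sds, dtype=float)


def extract_all(image, leaf_mask: np.ndarray | None = None,
                config: FeatureConfig | None = None) -> FeatureVector:
    """All 36 features of one image over its leaf mask.

    ``leaf_mask`` defaults to the image's ground-truth mask when present.
    """
    config = config or FeatureConfig()
    if leaf_mask is None:
        if image.truth is None:
            raise ValueError("no leaf mask given and image carries no truth")
        leaf_mask = image.truth.leaf_mask
    parts = [
        color_features(image.rgb, leaf_mask),
        histogram_features(image.gray, leaf_mask),
        ggcm_features(build_ggcm(image.gray, leaf_mask, config.ng, config.ns, config.t)),
        glcm_features(build_glcm(image.gray, leaf_mask, config.glcm_levels,
                                 config.glcm_distance)),
    ]
    return FeatureVector(values=np.concatenate(parts))


def feature_table(images, masks=None, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a list of images (rows indexed by image id)."""
    masks = masks if masks is not None else [None] * len(images)
    rows = [extract_all(img, m, config).values for img, m in zip(images, masks)]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES),
                        index=[img.id for img in images])
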