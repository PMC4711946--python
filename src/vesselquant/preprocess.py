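"""Pre-processing stage: clean a stained-section image and delimit the wall.

The stage converts the RGB image to CIELab, removes dark tissue folds and
blood residue, stretches the lightness contrast, binarizes with Otsu's
method and cleans the binary image with DBSCAN, producing the vessel-wall
mask whose pixel count A_TOT normalizes all downstream area measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import DBSCAN

from .config import ColorMask, DbscanConfig, FoldThresholdConfig, PipelineConfig

logger = logging.getLogger(__name__)

# label codes used by dbscan() for pixels that are not foreground / noise
NOT_FOREGROUND = -2
NOISE = -1


class DegenerateImageError(ValueError):
    """Raised when an image has no usable structure (empty, constant, ...)."""


class SegmentationFailure(RuntimeError):
    """Raised when no vessel-wall cluster can be identified."""


@dataclass(frozen=True)
class WallRegion:
    """Vessel-wall mask plus its area in pixels (A_TOT)."""

    mask: np.ndarray  # H×W bool, True on the wall
    a_tot: int

    def __post_init__(self) -> None:
        if self.a_tot != int(np.count_nonzero(self.mask)):
            raise ValueError("a_tot must equal the wall pixel count")


@dataclass(frozen=True)
class PreprocessResult:
    """All intermediate products of the pre-processing stage."""

    lab: np.ndarray            # H×W×3 original L*a*b* image
    fold_t: float              # dark-fold lightness threshold
    fold_mask: np.ndarray      # H×W bool defect mask
    blood_mask: np.ndarray     # H×W bool defect mask
    valid: np.ndarray          # H×W bool, False where defects were removed
    L_stretched: np.ndarray    # H×W float in [0,100], 0 on removed pixels
    otsu_T: float              # binarization threshold on [0,1]
    wall: WallRegion


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIELab (sRGB primaries, D65 white).

    Returns an H×W×3 float array with L* in [0,100].
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise DegenerateImageError(f"expected H×W×3 RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer):
            if img.min() < 0 or img.max() > 255:
                raise ValueError("integer RGB values must lie in [0, 255]")
            img = img.astype(np.uint8)
        else:
            raise ValueError("RGB image must be 8-bit integer")
    return rgb2lab(img)


def fold_threshold(L: np.ndarray, cfg: FoldThresholdConfig | None = None) -> float:
    """Lightness threshold below which pixels are treated as tissue folds.

    The threshold is half the location of the first predominant peak of the
    smoothed L* histogram, scanning from 0 upward.  A peak qualifies when
    its smoothed height is at least ``prominence_fraction`` times the global
    maximum.
    """
    cfg = cfg or FoldThresholdConfig()
    L = np.asarray(L, dtype=float).ravel()
    if L.size == 0:
        raise DegenerateImageError("empty lightness raster")
    centers = np.linspace(0.0, 100.0, cfg.n_bins)
    half = 50.0 / (cfg.n_bins - 1)
    edges = np.concatenate([centers - half, [centers[-1] + half]])
    hist, _ = np.histogram(L, bins=edges)
    kernel = np.ones(cfg.smoothing_window) / cfg.smoothing_window
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    floor = cfg.prominence_fraction * smooth.max()
    n = len(smooth)
    # scan runs of equal smoothed height; a run is a peak when it rises on
    # the left and falls on the right (plateaus locate at their center)
    s = 0
    while s < n:
        e = s
        while e + 1 < n and smooth[e + 1] == smooth[s]:
            e += 1
        left_ok = s == 0 or smooth[s] > smooth[s - 1]
        right_ok = e == n - 1 or smooth[e] > smooth[e + 1]
        if left_ok and right_ok and smooth[s] >= floor and smooth[s] > 0:
            peak = (centers[s] + centers[e]) / 2.0
            t = peak / 2.0
            logger.info("fold threshold t=%.2f (peak at L*=%.1f)", t, peak)
            return float(t)
        s = e + 1
    raise DegenerateImageError("no predominant peak in the lightness histogram")


def detect_folds(lab: np.ndarray, t: float) -> np.ndarray:
    """Binary defect mask of dark tissue folds: True where L* < t."""
    if not 0.0 <= t <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    return lab[..., 0] < t


def detect_blood(lab: np.ndarray, cm: ColorMask) -> np.ndarray:
    """Binary defect mask of blood residue: pixels within the color mask.

    A pixel is flagged when its Euclidean L*a*b* distance to ``cm.center``
    is at most ``cm.radius``.
    """
    center = np.asarray(cm.center, dtype=float)
    d2 = ((lab - center) ** 2).sum(axis=-1)
    return d2 <= cm.radius**2


def remove_defects(
    L: np.ndarray, masks: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out defect pixels in the lightness raster.

    Returns ``(L_clean, valid)``: defect pixels are set to 0 (the pixel-wise
    multiplication by the inverted binary masks) and flagged invalid so that
    later statistics (contrast-stretch extrema, Otsu histogram) skip them.
    """
    L = np.asarray(L, dtype=float)
    valid = np.ones(L.shape, dtype=bool)
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != L.shape:
            raise ValueError(f"defect mask shape {m.shape} != raster shape {L.shape}")
        valid &= ~m
    return np.where(valid, L, 0.0), valid


def contrast_stretch(L: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Remap valid lightness values affinely onto the full [0,100] range.

    Each valid pixel L is replaced by round(100·(L−Lmin)/(Lmax−Lmin)) where
    Lmin/Lmax are taken over valid pixels only.  Invalid pixels stay 0.
    """
    L = np.asarray(L, dtype=float)
    if valid is None:
        valid = np.ones(L.shape, dtype=bool)
    vals = L[valid]
    if vals.size == 0:
        raise DegenerateImageError("no valid pixels to stretch")
    lmin, lmax = float(vals.min()), float(vals.max())
    if lmax == lmin:
        raise DegenerateImageError("constant lightness raster: cannot stretch contrast")
    out = np.zeros_like(L)
    out[valid] = np.round(100.0 * (L[valid] - lmin) / (lmax - lmin))
    return out


def otsu_threshold(L01: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Otsu's threshold for a raster scaled to [0,1].

    Values are quantized to 256 levels; the exhaustive search maximizes the
    between-class variance with exact integer arithmetic, so the result is
    fully deterministic and ties resolve toward the lowest threshold.  The
    returned T is the decision boundary (k+0.5)/255 between the optimal
    split level k and k+1; classify a pixel as the dark class when v ≤ T.
    """
    L01 = np.asarray(L01, dtype=float)
    if valid is None:
        valid = np.ones(L01.shape, dtype=bool)
    vals = L01[valid]
    if vals.size == 0:
        raise DegenerateImageError("no valid pixels")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("raster must be scaled to [0,1]")
    levels = np.rint(vals * 255).astype(np.int64)
    counts = np.bincount(levels, minlength=256)
    N = int(counts.sum())
    S = int((np.arange(256) * counts).sum())
    # between-class variance at split k is (S0·N − S·N0)² / (N0·(N−N0)) up to
    # a constant factor; compared exactly via cross-multiplication
    best_k = None
    best_num = best_den = 0
    N0 = S0 = 0
    for k in range(255):
        N0 += int(counts[k])
        S0 += k * int(counts[k])
        if N0 == 0 or N0 == N:
            continue
        num = S0 * N - S * N0
        sc_num, sc_den = num * num, N0 * (N - N0)
        if best_k is None or sc_num * best_den > best_num * sc_den:
            best_k, best_num, best_den = k, sc_num, sc_den
    if best_k is None:
        raise DegenerateImageError("constant raster: Otsu threshold undefined")
    T = (best_k + 0.5) / 255.0
    logger.info("Otsu threshold T=%.4f", T)
    return T


def dbscan(mask: np.ndarray, cfg: DbscanConfig | None = None) -> np.ndarray:
    """Density-cluster the foreground pixels of a binary mask.

    Foreground pixels are data points; a pixel is a core pixel when the
    circle of radius R around it contains at least ``min_pxs`` foreground
    pixels (itself included).  Clusters are the density-connected components
    of core pixels plus reachable border pixels; the rest is noise.

    Returns an H×W integer label image: cluster ids ≥ 0, ``NOISE`` (−1) for
    noise pixels, ``NOT_FOREGROUND`` (−2) elsewhere.  Points are processed
    in row-major order, so the labeling is deterministic.
    """
    cfg = cfg or DbscanConfig()
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(mask.shape, NOT_FOREGROUND, dtype=np.int64)
    coords = np.argwhere(mask)  # row-major order
    if len(coords) == 0:
        return labels
    est = DBSCAN(eps=cfg.R, min_samples=cfg.min_pxs).fit(coords.astype(float))
    labels[mask] = est.labels_
    return labels


def pixel_area(mask: np.ndarray) -> int:
    """Area of a binary mask in pixels: the count of True pixels."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def clean_wall_mask(binary: np.ndarray, cfg: DbscanConfig | None = None) -> WallRegion:
    """Remove dust/dirt from the binarized image and return the wall region.

    Two density-clustering passes:

    1. cluster the wall-labeled (foreground) pixels and keep only the
       largest cluster — dust specks and other small objects are dropped;
    2. cluster the remaining non-wall pixels and keep the two largest
       clusters (the region outside the vessel and the lumen); every other
       non-wall cluster or noise pixel is merged back into the wall, which
       fills interior pinholes.
    """
    cfg = cfg or DbscanConfig()
    binary = np.asarray(binary, dtype=bool)
    labels = dbscan(binary, cfg)
    cluster_ids = labels[labels >= 0]
    if cluster_ids.size == 0:
        raise SegmentationFailure("no vessel-wall cluster found in binarized image")
    sizes = np.bincount(cluster_ids)
    wall = labels == int(np.argmax(sizes))

    bg = ~wall
    bg_labels = dbscan(bg, cfg)
    bg_ids = bg_labels[bg_labels >= 0]
    if bg_ids.size:
        bg_sizes = np.bincount(bg_ids)
        keep = np.argsort(bg_sizes)[::-1][:2]
        fill = bg & ~np.isin(bg_labels, keep)
    else:
        fill = bg
    wall = wall | fill
    return WallRegion(mask=wall, a_tot=pixel_area(wall))


def preprocess_image(
    rgb: np.ndarray, config: PipelineConfig | None = None
) -> PreprocessResult:
    """Run the full pre-processing stage on an RGB image."""
    config = config or PipelineConfig()
    lab = rgb_to_lab(rgb)
    L = lab[..., 0]
    t = fold_threshold(L, config.fold)
    folds = detect_folds(lab, t)
    blood = detect_blood(lab, config.blood)
    L_clean, valid = remove_defects(L, [folds, blood])
    L_stretched = contrast_stretch(L_clean, valid)
    T = otsu_threshold(L_stretched / 100.0, valid)
    binary = valid & (L_stretched / 100.0 <= T)  # wall is the dark class
    wall = clean_wall_mask(binary, config.dbscan)
    return PreprocessResult(
        lab=lab,
        fold_t=t,
        fold_mask=folds,
        blood_mask=blood,
        valid=valid,
        L_stretched=L_stretched,
        otsu_T=T,
        wall=wall,
    )
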