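"""Spatial regularity measures and image similarity measures.

Regularity measures quantify how structured (blob-like, localised) an ion
image is; all are reported both raw and *oriented* so that 1 = maximally
regular, 0 = maximally scattered:

* ``scatter_ratio`` — fraction of Otsu signal pixels lying outside the largest
  connected component (raw; oriented = 1 - raw).
* ``spatial_chaos`` — mean fraction of isolated signal pixels across a grid of
  quantile binarisation levels (raw; oriented = 1 - raw).  A variant of the
  edge-based "measure of chaos"; lower chaos = more structure.
* ``gini_index`` — concentration of the intensity distribution
  (0 = perfectly uniform); oriented = raw, since concentrated signal is
  localised signal.

Similarity measures compare an ion image to a reference: Pearson and Spearman
correlation on the flattened pixel vectors, mean local SSIM, and normalised
mutual information NMI = I(A;B) / sqrt(H(A) H(B)) on histogram-discretised
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import IonImage, ROIMask, otsu_mask
from .errors import DegenerateImageError, DimensionMismatchError, UndefinedScoreError

__all__ = [
    "RegularityScore",
    "SimilarityScore",
    "scatter_ratio",
    "spatial_chaos",
    "gini_index",
    "regularity",
    "similarity",
    "connected_components",
    "REGULARITY_MEASURES",
    "SIMILARITY_MEASURES",
]

REGULARITY_MEASURES = ("scatter_ratio", "spatial_chaos", "gini")
SIMILARITY_MEASURES = ("pearson", "spearman", "ssim", "nmi")

# 8-connectivity structuring element (diagonal contacts count); 4-connectivity
# is exposed as an option everywhere it matters.
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCT8
    if connectivity == 4:
        return _STRUCT4
    raise ValueError("connectivity must be 4 or 8")


def _values(img) -> np.ndarray:
    if isinstance(img, ROIMask):
        return img.mask.astype(float)
    return np.asarray(getattr(img, "values", img), dtype=float)


@dataclass(frozen=True)
class RegularityScore:
    value: float  # oriented: 1 = regular/localised
    raw: float
    measure: str
    oriented: bool = True


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    measure: str


def connected_components(mask: np.ndarray, connectivity: int = 8):
    """Label connected components of a boolean mask; returns (labels, n)."""
    return ndimage.label(np.asarray(mask, bool), structure=_structure(connectivity))


def scatter_ratio(img, connectivity: int = 8, n_bins: int = 256) -> RegularityScore:
    """Fraction of signal pixels not in the largest connected component.

    The image is binarised by Otsu; "scattered" pixels are signal pixels
    outside the largest 8-connected component (first-labelled largest on
    ties).  Raw score in [0, 1]; oriented regularity = 1 - raw.
    """
    mask = otsu_mask(_values(img), n_bins=n_bins)
    total = int(mask.sum())
    if total == 0:
        raise DegenerateImageError("no signal pixels above the Otsu threshold")
    labels, n = connected_components(mask, connectivity)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.max(sizes))  # argmax ties -> first label, size identical
    raw = (total - largest) / total
    return RegularityScore(value=1.0 - raw, raw=raw, measure="scatter_ratio")


def spatial_chaos(img, n_levels: int = 64, connectivity: int = 8) -> RegularityScore:
    """Mean isolated-pixel fraction over quantile binarisation levels.

    For each threshold on the quantile grid of the nonzero intensities the
    image is binarised (signal = value reaches the level, which keeps the
    zero background off since all levels are positive) and the fraction of
    signal pixels with no signal neighbour (8-neighbourhood) is recorded;
    chaos is the mean over levels that retain at least one signal pixel.
    """
    v = _values(img)
    if v.min() == v.max():
        raise DegenerateImageError("spatial chaos undefined on a constant image")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    nz = v[v > 0]
    if nz.size == 0:
        raise DegenerateImageError("spatial chaos undefined without positive pixels")
    qs = np.arange(n_levels) / n_levels
    thresholds = np.quantile(nz, qs)
    struct = _structure(connectivity).copy()
    struct[1, 1] = False  # neighbour count excludes the pixel itself
    fractions = []
    for t in np.unique(thresholds):
        mask = v >= t
        n_sig = int(mask.sum())
        if n_sig == 0:
            continue
        neighbours = ndimage.convolve(mask.astype(int), struct.astype(int), mode="constant")
        isolated = mask & (neighbours == 0)
        fractions.append(isolated.sum() / n_sig)
    if not fractions:
        raise DegenerateImageError("no binarisation level retains signal pixels")
    raw = float(np.mean(fractions))
    return RegularityScore(value=1.0 - raw, raw=raw, measure="spatial_chaos")


def gini_index(img) -> RegularityScore:
    """Gini concentration of the pixel intensity distribution.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 for a uniform image,
    -> (n-1)/n for signal concentrated in a single pixel.  Computed via the
    sorted-value identity rather than the O(n^2) double sum.
    """
    x = _values(img).ravel()
    if np.any(x < 0):
        raise ValueError("Gini index requires non-negative intensities")
    total = x.sum()
    if total <= 0:
        raise DegenerateImageError("Gini index undefined for an all-zero image")
    xs = np.sort(x)
    n = xs.size
    g = float((2.0 * np.sum(np.arange(1, n + 1) * xs)) / (n * total) - (n + 1.0) / n)
    return RegularityScore(value=g, raw=g, measure="gini")


def regularity(img, measure: str = "scatter_ratio", **kwargs) -> RegularityScore:
    """Dispatch to one of the oriented regularity measures."""
    if measure == "scatter_ratio":
        return scatter_ratio(img, **kwargs)
    if measure == "spatial_chaos":
        return spatial_chaos(img, **kwargs)
    if measure == "gini":
        return gini_index(img)
    raise ValueError(f"unknown regularity measure {measure!r}")


# ---------------------------------------------------------------------------
# similarity


def _nmi(a: np.ndarray, b: np.ndarray, bins_a: int, bins_b: int) -> float:
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=(bins_a, bins_b))
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz])))
    ha = -float(np.sum(pa[pa > 0] * np.log(pa[pa > 0])))
    hb = -float(np.sum(pb[pb > 0] * np.log(pb[pb > 0])))
    if ha <= 0 or hb <= 0:
        raise UndefinedScoreError("NMI undefined for a constant (zero-entropy) image")
    return mi / np.sqrt(ha * hb)


def _n_levels(img, default: int) -> int:
    # a binary mask keeps its two natural levels instead of 256 empty-ish bins
    if isinstance(img, ROIMask):
        return 2
    return default


def similarity(a, b, measure: str = "pearson", n_bins: int = 256) -> SimilarityScore:
    """Similarity between two images on the same grid.

    Correlations are computed on flattened pixel vectors and are undefined
    (raising :class:`UndefinedScoreError`) for constant input — filters map
    that to a failing -inf score.  SSIM is the mean local structural
    similarity with a Gaussian window (sigma 1.5) and the standard stabilising
    constants C1 = (0.01 L)^2, C2 = (0.03 L)^2 where L is the larger dynamic
    range of the pair.  NMI uses equal-width histograms (256 bins; a binary
    mask keeps its 2 levels) and geometric-mean normalisation.
    """
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise DimensionMismatchError(f"image shapes differ: {va.shape} vs {vb.shape}")
    fa, fb = va.ravel(), vb.ravel()
    if measure in ("pearson", "spearman"):
        if np.ptp(fa) == 0 or np.ptp(fb) == 0:
            raise UndefinedScoreError(f"{measure} undefined for constant input")
        if measure == "pearson":
            val = float(stats.pearsonr(fa, fb).statistic)
        else:
            val = float(stats.spearmanr(fa, fb).statistic)
    elif measure == "ssim":
        from skimage.metrics import structural_similarity

        L = float(max(np.ptp(fa), np.ptp(fb)))
        if L == 0:
            raise UndefinedScoreError("SSIM undefined: zero dynamic range")
        val = float(
            structural_similarity(
                va, vb, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=L, K1=0.01, K2=0.03,
            )
        )
    elif measure == "nmi":
        val = float(_nmi(fa, fb, _n_levels(a, n_bins), _n_levels(b, n_bins)))
    else:
        raise ValueError(f"unknown similarity measure {measure!r}")
    return SimilarityScore(value=val, measure=measure)
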