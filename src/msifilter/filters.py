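"""Reference-similarity filter and connected-pixel-count filter.

Both filters score every peak column and return a :class:`FilterResult`
with the scores, the boolean keep vector and the full parameter record.

* The reference filter keeps peaks whose ion image is similar (strictly above
  a threshold, default 0) to a reference image — typically the binary tissue
  ROI or a per-pixel summary image.  Matrix/solvent peaks live off tissue and
  anti-correlate with the ROI, so the default threshold already removes them
  while sparing ions confined to small sub-regions of the tissue.

* The count filter keeps peaks whose Otsu signal mask contains a connected
  component of at least ``min_pixels`` pixels inside the ROI; shot-noise
  signal scatters into near-isolated pixels and fails.  Higher aggressiveness
  levels additionally compare signal inside vs outside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MSIDataset, ROIMask, ReferenceImage, otsu_mask
from .errors import (
    DegenerateImageError,
    DimensionMismatchError,
    MSIFilterError,
    UndefinedScoreError,
)
from .metrics import connected_components, similarity

__all__ = ["FilterResult", "reference_filter", "count_filter", "all_ones_roi"]

FAIL_SCORE = float("-inf")  # sentinel for undefined/degenerate peak images


@dataclass
class FilterResult:
    """Per-peak scores and keep decisions of one filter application."""

    filter_name: str
    scores: np.ndarray
    keep: np.ndarray
    params: dict = field(default_factory=dict)
    pvalues: np.ndarray | None = None
    pvalues_adjusted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.scores.shape != self.keep.shape:
            raise MSIFilterError("scores and keep must have equal length")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_frame(self, ds: MSIDataset | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores, "keep": self.keep})
        if self.pvalues is not None:
            df["p"] = self.pvalues
            df["p_adjusted"] = self.pvalues_adjusted
        if ds is not None:
            df.insert(0, "peak_id", ds.peak_ids)
            df.insert(1, "mz", ds.mz)
        df["filter"] = self.filter_name
        return df


def all_ones_roi(shape: tuple[int, int]) -> ROIMask:
    """All-true ROI for datasets without off-tissue pixels."""
    return ROIMask.all_ones(shape)


def reference_filter(
    ds: MSIDataset,
    ref: ReferenceImage | ROIMask,
    measure: str = "spearman",
    threshold: float = 0.0,
) -> FilterResult:
    """Keep peaks whose ion image scores strictly above ``threshold`` against ``ref``.

    Constant (information-free) peak images receive the -inf sentinel and are
    dropped.  An all-ones ROI used with a correlation measure is rejected up
    front: a constant reference has no defined correlation with anything.
    """
    ref_shape = ref.shape
    if tuple(ref_shape) != tuple(ds.shape):
        raise DimensionMismatchError("reference shape does not match dataset grid")
    ref_flat = ref.flatten()
    if measure in ("pearson", "spearman") and np.ptp(np.asarray(ref_flat, float)) == 0:
        raise UndefinedScoreError(
            f"{measure} reference filter undefined for a constant reference "
            "(e.g. an all-ones ROI)"
        )
    scores = np.empty(ds.n_peaks)
    for i in range(ds.n_peaks):
        img = ds.ion_image(i)
        try:
            scores[i] = similarity(img, ref, measure=measure).value
        except UndefinedScoreError:
            scores[i] = FAIL_SCORE
    keep = scores > threshold
    return FilterResult(
        "reference",
        scores,
        keep,
        params={"measure": measure, "threshold": threshold, "reference": getattr(ref, "method", getattr(ref, "origin", "external"))},
    )


def count_filter(
    ds: MSIDataset,
    roi: ROIMask,
    min_pixels: int = 4,
    aggressive: int = 0,
    connectivity: int = 8,
) -> FilterResult:
    """Keep peaks with a large-enough connected signal component inside the ROI.

    Per peak, the ion image is Otsu-binarised and its signal mask labelled
    into connected components; the score is the size of the largest
    ROI-restricted component part.  Aggressiveness levels nest:

    * 0 — some component intersecting the ROI has >= ``min_pixels`` pixels
      inside the ROI;
    * 1 — additionally the largest ROI-restricted component part is at least
      as large as the largest component lying fully outside the ROI;
    * 2 — additionally the total signal pixel count inside the ROI exceeds
      the count outside.

    Under an all-ones ROI levels 1 and 2 reduce to level 0.
    """
    if tuple(roi.shape) != tuple(ds.shape):
        raise DimensionMismatchError("ROI shape does not match dataset grid")
    if not roi.mask.any():
        raise MSIFilterError("count filter requires a non-empty ROI")
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    if aggressive not in (0, 1, 2):
        raise ValueError("aggressiveness level must be 0, 1 or 2")

    scores = np.zeros(ds.n_peaks)
    keep = np.zeros(ds.n_peaks, dtype=bool)
    for i in range(ds.n_peaks):
        img = ds.ion_image(i)
        try:
            mask = otsu_mask(img.values)
        except DegenerateImageError:
            scores[i] = FAIL_SCORE
            continue
        labels, n = connected_components(mask, connectivity)
        if n == 0:
            scores[i] = FAIL_SCORE
            continue
        idx = np.arange(1, n + 1)
        size_in = np.bincount(labels[roi.mask].ravel(), minlength=n + 1)[1:]
        size_total = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        size_out = size_total - size_in
        largest_in = int(size_in.max()) if n else 0
        outside_only = size_total[size_in == 0]
        largest_outside = int(outside_only.max()) if outside_only.size else 0
        scores[i] = largest_in
        ok = largest_in >= min_pixels
        if aggressive >= 1:
            ok = ok and largest_in >= largest_outside
        if aggressive >= 2:
            ok = ok and int(size_in.sum()) > int(size_out.sum())
        keep[i] = ok
    return FilterResult(
        "count",
        scores,
        keep,
        params={
            "min_pixels": min_pixels,
            "aggressive": aggressive,
            "connectivity": connectivity,
            "roi": roi.origin,
        },
    )
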