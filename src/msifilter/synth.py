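"""Synthetic MSI datasets with known ground truth.

Emulates the signal classes a spatial peak filter must separate:

* **structured** peaks — smooth intensity fields supported on a tissue-shaped
  ROI (thresholded smoothed random field occupying roughly 30–60% of the
  grid) plus low-level additive noise everywhere;
* **off_tissue** peaks — the same construction on the ROI complement
  (matrix/solvent-type signal);
* **noise** peaks — Bernoulli pixel processes with uniform intensity marks,
  the pixel-grid analogue of homogeneous-Poisson shot noise;
* **split groups** — a structured image partitioned across 2–3 columns by
  random pixel assignment, at m/z values jittered within 10 ppm.

Everything is reproducible from the seed; the truth object records per-peak
labels, the true ROI and the planted split groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import MSIDataset, ROIMask
from .errors import MSIFilterError

__all__ = ["SyntheticTruth", "generate", "write_fixture"]

LABELS = ("structured", "off_tissue", "noise", "split_member")


@dataclass
class SyntheticTruth:
    labels: list[str]
    roi_true: ROIMask
    split_groups: list[list[int]]
    split_true_images: list[np.ndarray]
    seed: int
    params: dict = field(default_factory=dict)

    def indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="nearest")


def _tissue_roi(rng: np.random.Generator, shape) -> np.ndarray:
    """Smooth blob covering ~30-60% of the grid."""
    field_ = _smooth_field(rng, shape, sigma=min(shape) / 8.0)
    frac = rng.uniform(0.35, 0.55)
    mask = field_ > np.quantile(field_, 1.0 - frac)
    return mask


def _structured_image(
    rng: np.random.Generator, support: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Smooth positive field on the support, additive noise everywhere."""
    shape = support.shape
    base = _smooth_field(rng, shape, sigma=min(shape) / 16.0)
    base = (base - base.min()) / (base.max() - base.min())  # [0, 1]
    img = (0.3 + 0.7 * base) * support
    img = img + rng.normal(0.0, noise_sd, size=shape)
    return np.clip(img, 0.0, None)


def _noise_image(rng: np.random.Generator, shape, density: float = 0.05) -> np.ndarray:
    hits = rng.random(shape) < density
    marks = rng.uniform(0.5, 1.0, size=shape)
    return hits * marks


def _mz_axis(rng: np.random.Generator, n: int, lo=500.0, hi=900.0, min_ppm=50.0) -> np.ndarray:
    """n sorted m/z values in [lo, hi], pairwise >= min_ppm apart."""
    mz = np.sort(rng.uniform(lo, hi, size=n))
    for _ in range(200):
        gaps_ok = np.diff(mz) > min_ppm * 1e-6 * mz[1:]
        if gaps_ok.all():
            return mz
        bad = np.flatnonzero(~gaps_ok) + 1
        mz[bad] = rng.uniform(lo, hi, size=bad.size)
        mz = np.sort(mz)
    raise MSIFilterError("could not draw a well-spaced m/z axis")


def generate(
    shape: tuple[int, int] = (64, 64),
    n_structured: int = 20,
    n_off_tissue: int = 15,
    n_noise: int = 15,
    n_split_groups: int = 0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[MSIDataset, SyntheticTruth]:
    """Generate a labelled synthetic dataset; fully reproducible from ``seed``."""
    if min(shape) < 16:
        raise MSIFilterError("grid must be at least 16x16 for meaningful spatial structure")
    n_split_members_max = 3
    n_total_slots = n_structured + n_off_tissue + n_noise + n_split_groups * n_split_members_max
    if n_total_slots == 0:
        raise MSIFilterError("at least one peak required")
    rng = np.random.default_rng(seed)
    roi = _tissue_roi(rng, shape)

    columns: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(n_structured):
        columns.append(_structured_image(rng, roi, noise_sd).ravel())
        labels.append("structured")
    for _ in range(n_off_tissue):
        columns.append(_structured_image(rng, ~roi, noise_sd).ravel())
        labels.append("off_tissue")
    for _ in range(n_noise):
        columns.append(_noise_image(rng, shape).ravel())
        labels.append("noise")

    # base m/z for every non-split peak plus one per split group
    base_mz = _mz_axis(rng, len(columns) + n_split_groups)
    assigned = base_mz[: len(columns)].copy()
    rng.shuffle(assigned)  # decouple label blocks from m/z order
    peak_mz = list(assigned)
    group_base_mz = base_mz[len(columns):]

    split_cols: list[np.ndarray] = []
    split_mz: list[float] = []
    split_true: list[np.ndarray] = []
    split_sizes: list[int] = []
    for g in range(n_split_groups):
        true_img = _structured_image(rng, roi, noise_sd)
        k = int(rng.integers(2, n_split_members_max + 1))
        assign = rng.integers(0, k, size=shape)
        members = [(true_img * (assign == j)).ravel() for j in range(k)]
        # members sit within <10 ppm of each other around the group base m/z
        offsets = np.sort(rng.uniform(0.0, 9.0, size=k)) * 1e-6 * group_base_mz[g]
        for j in range(k):
            split_cols.append(members[j])
            split_mz.append(float(group_base_mz[g] + offsets[j]))
        split_true.append(true_img)
        split_sizes.append(k)

    all_cols = columns + split_cols
    all_mz = np.array(peak_mz + split_mz)
    all_labels = labels + ["split_member"] * len(split_cols)
    order = np.argsort(all_mz)
    mat = np.stack(all_cols, axis=1)[:, order]
    mz_sorted = all_mz[order]
    labels_sorted = [all_labels[i] for i in order]

    # map planted group membership into sorted-column indices
    pos = np.empty(order.size, dtype=int)
    pos[order] = np.arange(order.size)
    split_groups = []
    cursor = len(columns)
    for k in split_sizes:
        split_groups.append(sorted(int(pos[cursor + j]) for j in range(k)))
        cursor += k

    ds = MSIDataset(mat, mz_sorted, shape)
    truth = SyntheticTruth(
        labels=labels_sorted,
        roi_true=ROIMask(roi, origin="external"),
        split_groups=split_groups,
        split_true_images=split_true,
        seed=seed,
        params={
            "shape": tuple(shape),
            "n_structured": n_structured,
            "n_off_tissue": n_off_tissue,
            "n_noise": n_noise,
            "n_split_groups": n_split_groups,
            "noise_sd": noise_sd,
        },
    )
    return ds, truth


def write_fixture(out_dir, seed: int = 0, **kwargs):
    """Write an imzML dataset plus a truth-label TSV for CLI use."""
    from pathlib import Path

    import pandas as pd

    from .core import save_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = generate(seed=seed, **kwargs)
    save_dataset(ds, out / "synthetic.imzML")
    pd.DataFrame(
        {"peak_id": ds.peak_ids, "mz": ds.mz, "label": truth.labels}
    ).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    np.savetxt(out / "roi_true.tsv", truth.roi_true.mask.astype(int), fmt="%d", delimiter="\t")
    return ds, truth
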