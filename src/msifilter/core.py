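"""MSI data model: dataset container, ion images, references and ROI detection.

An MSI dataset is a pixel x peak intensity matrix acquired on a 2-D raster.
Pixels are stored in row-major grid order (row, then column), 0-based
everywhere; imzML 1-based x/y coordinates map as ``col = x - 1``,
``row = y - 1``.  One m/z value (and a stable string identifier) is attached
to each peak column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateImageError, DimensionMismatchError, MSIFilterError

__all__ = [
    "MSIDataset",
    "IonImage",
    "ROIMask",
    "ReferenceImage",
    "load_dataset",
    "save_dataset",
    "ion_image",
    "make_reference",
    "tic_image",
    "otsu_threshold",
    "otsu_mask",
    "detect_roi",
    "image_from_array",
]

REFERENCE_METHODS = ("sum", "mean", "median", "pca1")


@dataclass(frozen=True)
class IonImage:
    """One peak's intensities reshaped onto the 2-D pixel grid."""

    values: np.ndarray
    peak_id: str = ""
    mz: float = float("nan")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise MSIFilterError("ion image must be 2-D")
        if not np.all(np.isfinite(v)):
            raise MSIFilterError("ion image contains non-finite values")
        if np.any(v < 0):
            raise MSIFilterError("ion image contains negative intensities")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        """Row-major pixel vector; exact inverse of :func:`ion_image`."""
        return self.values.reshape(-1)


@dataclass(frozen=True)
class ReferenceImage:
    """A per-pixel summary of the whole dataset, used as filter reference/covariate."""

    values: np.ndarray
    method: str = "external"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise MSIFilterError("reference image must be 2-D")
        if not np.all(np.isfinite(v)):
            raise MSIFilterError("reference image contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask over the pixel grid (True = on tissue)."""

    mask: np.ndarray
    origin: str = "external"  # otsu | kmeans | external | all_ones

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise MSIFilterError("ROI mask must be 2-D")
        m = m.astype(bool)
        if self.origin != "all_ones" and not m.any():
            raise MSIFilterError("ROI mask has no true pixel")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def flatten(self) -> np.ndarray:
        return self.mask.reshape(-1)

    @staticmethod
    def all_ones(shape: tuple[int, int]) -> "ROIMask":
        """Degenerate all-true ROI for datasets without off-tissue pixels."""
        return ROIMask(np.ones(shape, dtype=bool), origin="all_ones")


@dataclass
class MSIDataset:
    """Peak-matched MSI dataset: pixel x peak matrix + m/z axis + grid shape.

    Rows of ``intensities`` are pixels in row-major grid order; columns are
    matched peaks with strictly increasing ``mz``.
    """

    intensities: np.ndarray
    mz: np.ndarray
    shape: tuple[int, int]
    peak_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        nr, nc = int(self.shape[0]), int(self.shape[1])
        self.shape = (nr, nc)
        if nr <= 0 or nc <= 0:
            raise MSIFilterError("grid shape must be positive")
        if self.intensities.ndim != 2:
            raise MSIFilterError("intensity matrix must be 2-D (pixels x peaks)")
        if self.intensities.shape[0] != nr * nc:
            raise MSIFilterError(
                f"pixel count {self.intensities.shape[0]} != grid product {nr * nc}"
            )
        if self.mz.ndim != 1 or self.mz.size != self.intensities.shape[1]:
            raise MSIFilterError("m/z vector length must equal the number of peak columns")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise MSIFilterError("m/z vector must be strictly increasing")
        if np.any(self.intensities < 0):
            raise MSIFilterError("negative intensities are not allowed")
        if not np.all(np.isfinite(self.intensities)):
            raise MSIFilterError("non-finite intensities are not allowed")
        if not self.peak_ids:
            self.peak_ids = [f"mz_{m:.4f}" for m in self.mz]
        if len(self.peak_ids) != self.mz.size:
            raise MSIFilterError("peak_ids length must equal the number of peaks")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    def ion_image(self, peak: int) -> IonImage:
        return ion_image(self, peak)

    def tic_image(self) -> ReferenceImage:
        return tic_image(self)

    def subset(self, keep: np.ndarray) -> "MSIDataset":
        """New dataset restricted to the peaks where ``keep`` is True (or indexed)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return MSIDataset(
            self.intensities[:, idx],
            self.mz[idx],
            self.shape,
            [self.peak_ids[i] for i in idx],
        )

    def copy(self) -> "MSIDataset":
        return MSIDataset(
            self.intensities.copy(), self.mz.copy(), self.shape, list(self.peak_ids)
        )


# ---------------------------------------------------------------------------
# image extraction and references


def ion_image(ds: MSIDataset, peak: int) -> IonImage:
    """Reshape one peak column onto the pixel grid (row-major)."""
    if not 0 <= peak < ds.n_peaks:
        raise IndexError(f"peak index {peak} out of range [0, {ds.n_peaks})")
    values = ds.intensities[:, peak].reshape(ds.shape)
    return IonImage(values, peak_id=ds.peak_ids[peak], mz=float(ds.mz[peak]))


def tic_image(ds: MSIDataset) -> ReferenceImage:
    """Total-ion-count image: per-pixel sum over all peaks."""
    if ds.n_peaks == 0:
        raise MSIFilterError("empty dataset")
    return ReferenceImage(ds.intensities.sum(axis=1).reshape(ds.shape), method="sum")


def make_reference(ds: MSIDataset, method: str = "sum") -> ReferenceImage:
    """Build a reference image from the full peak set.

    ``sum``/``mean``/``median`` are per-pixel statistics across peaks; ``pca1``
    is the first principal-component score of the (column-centred) pixel x peak
    matrix, sign-fixed so the scores correlate non-negatively with the TIC.
    """
    if ds.n_peaks == 0:
        raise MSIFilterError("empty dataset")
    if method == "sum":
        vals = ds.intensities.sum(axis=1)
    elif method == "mean":
        vals = ds.intensities.mean(axis=1)
    elif method == "median":
        vals = np.median(ds.intensities, axis=1)
    elif method == "pca1":
        if ds.n_peaks < 2:
            raise MSIFilterError("pca1 reference requires at least 2 peaks")
        X = ds.intensities
        if np.allclose(X, X[0]):
            raise DegenerateImageError("pca1 reference undefined on constant data")
        from sklearn.decomposition import PCA

        scores = PCA(n_components=1, random_state=0).fit_transform(X)[:, 0]
        tic = X.sum(axis=1)
        # PC sign is arbitrary; fix it against the TIC for reproducibility
        if np.corrcoef(scores, tic)[0, 1] < 0:
            scores = -scores
        vals = scores
    else:
        raise ValueError(f"unknown reference method {method!r}")
    return ReferenceImage(vals.reshape(ds.shape), method=method)


# ---------------------------------------------------------------------------
# Otsu thresholding


def otsu_threshold(img, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    The histogram uses ``n_bins`` equal-width bins over [min, max]; candidate
    thresholds are the interior bin edges and the returned value equals an
    exhaustive search over them.  Pixels strictly greater than the threshold
    are "signal".
    """
    x = np.sort(np.asarray(getattr(img, "values", img), dtype=float).ravel())
    lo, hi = float(x[0]), float(x[-1])
    if lo == hi:
        raise DegenerateImageError("cannot threshold a constant image")
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]  # interior edges = candidates
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    n0 = np.searchsorted(x, edges, side="right")  # class 0: values <= edge
    n1 = n - n0
    valid = (n0 > 0) & (n1 > 0)
    mu0 = np.where(valid, prefix[n0] / np.maximum(n0, 1), 0.0)
    mu1 = np.where(valid, (prefix[n] - prefix[n0]) / np.maximum(n1, 1), 0.0)
    var_between = np.where(valid, n0 * n1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(var_between))  # ties -> lowest edge
    return float(edges[best])


def otsu_mask(img, n_bins: int = 256) -> np.ndarray:
    """Boolean signal mask: pixels strictly above the Otsu threshold."""
    values = np.asarray(getattr(img, "values", img), dtype=float)
    return values > otsu_threshold(values, n_bins=n_bins)


# ---------------------------------------------------------------------------
# ROI detection


def detect_roi(
    ds: MSIDataset,
    method: str = "otsu",
    reference: ReferenceImage | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> ROIMask:
    """Detect the expected signal-source region (tissue).

    ``otsu`` thresholds a reference image (per-pixel sum by default);
    ``kmeans`` runs 2-means on the pixel intensity vectors and keeps the
    cluster with the larger mean TIC.
    """
    if method == "otsu":
        if reference is None:
            reference = make_reference(ds, "sum")
        if reference.shape != ds.shape:
            raise DimensionMismatchError("reference shape does not match dataset grid")
        mask = reference.values > otsu_threshold(reference)
        return ROIMask(mask, origin="otsu")
    if method == "kmeans":
        X = ds.intensities
        if np.allclose(X, X[0]):
            raise DegenerateImageError("k-means ROI undefined on constant data")
        from sklearn.cluster import KMeans

        labels = KMeans(
            n_clusters=2, n_init=n_restarts, random_state=seed
        ).fit_predict(X)
        tic = X.sum(axis=1)
        mean0 = tic[labels == 0].mean()
        mean1 = tic[labels == 1].mean()
        roi_label = 0 if mean0 >= mean1 else 1
        return ROIMask((labels == roi_label).reshape(ds.shape), origin="kmeans")
    raise ValueError(f"unknown ROI method {method!r}")


def image_from_array(array: np.ndarray, shape: tuple[int, int] | None = None) -> ReferenceImage:
    """Convert an arbitrary pixel-intensity matrix into a reference image.

    The raster must already be registered to the MSI grid; when ``shape`` is
    given it is checked against the array dimensions (registration/resampling
    is out of scope).
    """
    arr = np.asarray(array, dtype=float)
    if arr.ndim == 3:  # RGB(A) raster -> luminance
        arr = arr[..., :3].mean(axis=2)
    if shape is not None and tuple(arr.shape) != tuple(shape):
        raise DimensionMismatchError(
            f"external image shape {arr.shape} does not match grid {tuple(shape)}"
        )
    return ReferenceImage(arr, method="external")


# ---------------------------------------------------------------------------
# I/O


def load_dataset(
    path: str | Path,
    format: str | None = None,
    shape: tuple[int, int] | None = None,
) -> MSIDataset:
    """Load a peak-matched dataset from imzML or a delimited matrix file.

    imzML pixels are placed at ``(row, col) = (y-1, x-1)``; grid cells with no
    recorded spectrum are zero-filled (with a warning).  Processed-mode imzML
    is accepted only when all spectra share one m/z axis (i.e. the peaks were
    matched upstream); ragged axes raise, since peak matching is out of scope.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "matrix"
    if format == "imzml":
        return _load_imzml(path)
    if format == "matrix":
        return _load_matrix(path, shape=shape)
    raise ValueError(f"unknown format {format!r}")


def _load_imzml(path: Path) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray([(x, y) for (x, y, *_z) in parser.coordinates])
    n_cols = int(coords[:, 0].max())
    n_rows = int(coords[:, 1].max())
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    mat = np.zeros((n_rows * n_cols, mz0.size))
    seen = np.zeros(n_rows * n_cols, dtype=bool)
    for i, (x, y) in enumerate(coords):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        if mzs.size != mz0.size or not np.allclose(mzs, mz0, rtol=1e-8, atol=1e-6):
            raise MSIFilterError(
                "processed-mode imzML without a common m/z axis: peaks are not "
                "matched; run peak matching upstream"
            )
        row, col = int(y) - 1, int(x) - 1
        pix = row * n_cols + col
        if seen[pix]:
            raise MSIFilterError(f"duplicate imzML coordinate (x={x}, y={y})")
        seen[pix] = True
        mat[pix] = np.asarray(ints, dtype=float)
    n_missing = int((~seen).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} of {seen.size} grid cells have no spectrum; zero-filled",
            stacklevel=3,
        )
    mat = np.clip(mat, 0.0, None)
    return MSIDataset(mat, mz0, (n_rows, n_cols))


def _load_matrix(path: Path, shape: tuple[int, int] | None = None) -> MSIDataset:
    """Delimited matrix: optional ``# shape: R C`` comment, header row of m/z values,
    then one row per pixel (row-major)."""
    header_shape = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#"):
            tokens = first.lstrip("#").replace("shape:", "").split()
            header_shape = (int(tokens[0]), int(tokens[1]))
            mz_line = fh.readline()
        else:
            mz_line = first
        mz = np.asarray(mz_line.replace(",", "\t").split(), dtype=float)
        mat = np.loadtxt(fh, delimiter=None)
    mat = np.atleast_2d(mat)
    if shape is None:
        shape = header_shape
    if shape is None:
        raise MSIFilterError("grid shape required: pass shape= or add a '# shape: R C' header")
    return MSIDataset(mat, mz, shape)


def save_dataset(ds: MSIDataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset to imzML (continuous mode) or a delimited matrix file."""
    path = Path(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "matrix"
    if format == "imzml":
        from pyimzml.ImzMLWriter import ImzMLWriter

        n_rows, n_cols = ds.shape
        with ImzMLWriter(str(path), mode="continuous") as w:
            for row in range(n_rows):
                for col in range(n_cols):
                    w.addSpectrum(ds.mz, ds.intensities[row * n_cols + col], (col + 1, row + 1, 1))
        return path
    if format == "matrix":
        with open(path, "w") as fh:
            fh.write(f"# shape: {ds.shape[0]} {ds.shape[1]}\n")
            fh.write("\t".join(f"{m:.6f}" for m in ds.mz) + "\n")
            np.savetxt(fh, ds.intensities, delimiter="\t", fmt="%.8g")
        return path
    raise ValueError(f"unknown format {format!r}")
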