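"""Complete-spatial-randomness tests on binarised ion images.

A peak whose Otsu signal pixels look like a homogeneous spatial Poisson
process carries no spatial information; informative ions cluster on tissue
structures.  Signal pixels define a 2-D point pattern inside the rectangular
pixel grid, tested with either

* the Clark–Evans nearest-neighbour index
  R = d̄_obs / d̄_exp, d̄_exp = 1 / (2 sqrt(lambda)), lambda = n / area,
  z = (d̄_obs - d̄_exp) / SE, SE = 0.26136 / sqrt(n lambda),
  one-sided towards aggregation (R < 1) by default; or

* a Kolmogorov–Smirnov test of the covariate values at the pattern points
  against the covariate distribution over the whole window (the CSR
  prediction): D = sup |F̂_points - F_window|.

p-values are adjusted across the peak set (Bonferroni by default) and peaks
that fail to reject CSR are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.spatial import cKDTree

from .core import MSIDataset, ReferenceImage, otsu_mask
from .errors import DegenerateImageError, DimensionMismatchError, MSIFilterError
from .filters import FilterResult

__all__ = [
    "PointPattern",
    "CSRTestResult",
    "clark_evans",
    "ks_covariate",
    "csr_select",
]


@dataclass(frozen=True)
class PointPattern:
    """Point locations inside a rectangular window (pixel units).

    Points are (row, col) coordinates — pixel centres when derived from a
    binarised image, but arbitrary unique positions inside the window are
    accepted (e.g. for null simulations).
    """

    points: np.ndarray
    window: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 2:
            raise MSIFilterError("point pattern needs >= 1 (row, col) points")
        nr, nc = self.window
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > nr) or np.any(
            pts[:, 1] < 0
        ) or np.any(pts[:, 1] > nc):
            raise MSIFilterError("points fall outside the window")
        if np.unique(pts, axis=0).shape[0] != pts.shape[0]:
            raise MSIFilterError("points must be unique")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return float(self.window[0] * self.window[1])

    @staticmethod
    def from_mask(mask: np.ndarray) -> "PointPattern":
        """Signal-pixel centres of a boolean image as a point pattern."""
        mask = np.asarray(mask, bool)
        pts = np.argwhere(mask).astype(float) + 0.5
        return PointPattern(pts, mask.shape)


@dataclass(frozen=True)
class CSRTestResult:
    statistic: float  # Clark-Evans R or KS D
    p: float
    method: str
    z: float = float("nan")  # Clark-Evans only
    n: int = 0
    p_adjusted: float = float("nan")


def _nn_distances(pts: np.ndarray, window=None, toroidal: bool = False) -> np.ndarray:
    if toroidal:
        boxsize = [float(window[0]), float(window[1])]
        tree = cKDTree(pts, boxsize=boxsize)
    else:
        tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def clark_evans(
    pp: PointPattern,
    correction: str = "none",
    alternative: str = "clustered",
) -> CSRTestResult:
    """Clark–Evans nearest-neighbour test of complete spatial randomness.

    ``correction``:

    * ``none`` — raw mean NN distance.  Conservative towards the clustered
      alternative: border points have inflated NN distances, biasing R up.
    * ``toroidal`` — distances on the torus; exactly calibrated under CSR.
    * ``donnelly`` — Donnelly's expectation/variance adjustment for
      rectangular windows.

    ``alternative``: ``clustered`` (one-sided, R < 1), ``regular`` (R > 1) or
    ``two-sided``.
    """
    if pp.n < 2:
        raise MSIFilterError("Clark-Evans test requires at least 2 points")
    lam = pp.n / pp.area
    d_obs = float(np.mean(_nn_distances(pp.points, pp.window, toroidal=correction == "toroidal")))
    if correction == "donnelly":
        nr, nc = pp.window
        perimeter = 2.0 * (nr + nc)
        d_exp = 0.5 / np.sqrt(lam) + (0.0514 + 0.041 / np.sqrt(pp.n)) * perimeter / pp.n
        se = np.sqrt(0.070 * pp.area / pp.n**2 + 0.037 * perimeter * np.sqrt(pp.area / pp.n**5))
    elif correction in ("none", "toroidal"):
        d_exp = 0.5 / np.sqrt(lam)
        se = 0.26136 / np.sqrt(pp.n * lam)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    R = d_obs / (0.5 / np.sqrt(lam))
    z = (d_obs - d_exp) / se
    if alternative == "clustered":
        p = float(stats.norm.cdf(z))
    elif alternative == "regular":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return CSRTestResult(statistic=float(R), p=p, method="clark_evans", z=float(z), n=pp.n)


def ks_covariate(
    pp: PointPattern,
    covariate: ReferenceImage,
    finite_population: bool = True,
) -> CSRTestResult:
    """KS test of the covariate distribution at pattern points vs the window.

    Under CSR the covariate values observed at the points are a uniform draw
    from the covariate values over all window pixels, so their empirical CDF
    must match the window CDF; D is the sup-norm distance between the two
    (right-continuous, evaluated at every distinct covariate value).  The
    p-value uses the asymptotic Kolmogorov distribution with effective sample
    size n/(1 - n/N) by default — pattern points are a without-replacement
    sample of the N window pixels, which shrinks the null fluctuations of D
    by sqrt(1 - n/N).  Set ``finite_population=False`` for the plain sqrt(n)
    scaling.
    """
    cov = np.asarray(covariate.values, dtype=float)
    if tuple(cov.shape) != tuple(pp.window):
        raise DimensionMismatchError("covariate shape does not match the window")
    if np.ptp(cov) == 0:
        raise DegenerateImageError("KS covariate test undefined for a constant covariate")
    rows = np.clip(pp.points[:, 0].astype(int), 0, cov.shape[0] - 1)
    cols = np.clip(pp.points[:, 1].astype(int), 0, cov.shape[1] - 1)
    at_points = np.sort(cov[rows, cols])
    window_vals = np.sort(cov.ravel())
    n, N = at_points.size, window_vals.size
    grid = np.unique(window_vals)
    F_pts = np.searchsorted(at_points, grid, side="right") / n
    F_win = np.searchsorted(window_vals, grid, side="right") / N
    D = float(np.max(np.abs(F_pts - F_win)))
    if n >= N:
        p = 1.0
    else:
        n_eff = n / (1.0 - n / N) if finite_population else float(n)
        p = float(special.kolmogorov(np.sqrt(n_eff) * D))
    return CSRTestResult(statistic=D, p=min(max(p, 0.0), 1.0), method="ks_covariate", n=n)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment {method!r}")


def csr_select(
    ds: MSIDataset,
    method: str = "ks_covariate",
    covariate: ReferenceImage | None = None,
    adjust: str = "bonferroni",
    alpha: float = 0.001,
    correction: str = "none",
    finite_population: bool = True,
    exclude_self: bool = False,
) -> FilterResult:
    """Keep peaks whose binarised signal rejects complete spatial randomness.

    Every peak contributes to the multiplicity correction, including
    degenerate ones (conservative); degenerate images and patterns with fewer
    than 2 points are dropped with p = 1 recorded.

    ``exclude_self`` subtracts the tested peak's own ion image from the
    covariate before the KS test.  Use it when the covariate is a sum-type
    image (TIC) that contains the peak itself: the self-contribution makes
    the covariate dependent on the pattern under the null and biases the test
    towards rejection when the peak set is small.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method == "ks_covariate" and covariate is None:
        raise MSIFilterError("ks_covariate requires a covariate image")
    pvals = np.ones(ds.n_peaks)
    statistic = np.full(ds.n_peaks, np.nan)
    testable = np.zeros(ds.n_peaks, dtype=bool)
    for i in range(ds.n_peaks):
        img = ds.ion_image(i)
        try:
            mask = otsu_mask(img.values)
        except DegenerateImageError:
            continue
        if mask.sum() < 2:
            continue
        pp = PointPattern.from_mask(mask)
        if method == "clark_evans":
            res = clark_evans(pp, correction=correction)
        elif method == "ks_covariate":
            cov = covariate
            if exclude_self:
                loo = np.clip(covariate.values - img.values, 0.0, None)
                if np.ptp(loo) == 0:
                    continue  # covariate was this peak alone
                cov = ReferenceImage(loo, method=covariate.method)
            res = ks_covariate(pp, cov, finite_population=finite_population)
        else:
            raise ValueError(f"unknown CSR test {method!r}")
        pvals[i] = res.p
        statistic[i] = res.statistic
        testable[i] = True
    p_adj = _adjust(pvals, adjust)
    keep = testable & (p_adj < alpha)
    return FilterResult(
        "csr",
        scores=p_adj,
        keep=keep,
        params={
            "method": method,
            "adjust": adjust,
            "alpha": alpha,
            "correction": correction,
            "covariate": None if covariate is None else covariate.method,
        },
        pvalues=pvals,
        pvalues_adjusted=p_adj,
    )
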