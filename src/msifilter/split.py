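"""Detection and merging of split peaks.

Random peak shifts during upstream peak matching can assign one ion source to
several contiguous m/z bins within the instrumental mass error.  Such "split"
peaks are recognised because their signal images occupy small or
non-overlapping spatial regions that, once merged, form an image at least as
regular as any of the parts.  Merging must run before any other filter, since
the other filters score exactly the spatial structure that splitting destroys.

Merge decision for a candidate group (columns within ``tol_ppm`` of their
neighbours, transitively chained):

i.   every pairwise overlap |A∩B| / min(|A|,|B|) of the Otsu signal masks is
     at most ``overlap_max``;
ii.  at least one member image has oriented regularity >= ``regularity_min``;
iii. the pixel-wise summed image has oriented regularity at least as high as
     the best member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IonImage, MSIDataset, otsu_mask
from .errors import DegenerateImageError, MSIFilterError
from .metrics import regularity

__all__ = [
    "MergePlan",
    "find_split_candidates",
    "evaluate_merge",
    "apply_merge",
    "split_merge",
]


@dataclass
class MergePlan:
    """Disjoint groups of column indices to merge, with diagnostics."""

    groups: list[list[int]] = field(default_factory=list)
    merged_mz: list[float] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            if len(g) < 2:
                raise MSIFilterError("merge groups must have at least 2 members")
            if seen & set(g):
                raise MSIFilterError("merge groups must be pairwise disjoint")
            seen |= set(g)
        if len(self.merged_mz) != len(self.groups):
            raise MSIFilterError("one merged m/z required per group")

    def __len__(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, (g, mz, diag) in enumerate(
            zip(self.groups, self.merged_mz, self.diagnostics or [{}] * len(self.groups))
        ):
            rows.append(
                {
                    "group": gid,
                    "members": ",".join(map(str, g)),
                    "member_mz": ",".join(f"{m:.6f}" for m in diag.get("member_mz", [])),
                    "merged_mz": mz,
                    "max_overlap": diag.get("max_overlap", np.nan),
                    "max_member_regularity": diag.get("max_member_regularity", np.nan),
                    "merged_regularity": diag.get("merged_regularity", np.nan),
                    "merge": diag.get("merge", True),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "group", "members", "member_mz", "merged_mz", "max_overlap",
                "max_member_regularity", "merged_regularity", "merge",
            ],
        )


def find_split_candidates(ds: MSIDataset, tol_ppm: float = 10.0) -> list[list[int]]:
    """Groups of adjacent peaks whose m/z gaps are within the ppm tolerance.

    Adjacent sorted peaks i, j=i+1 are linked when
    ``|mz_i - mz_j| <= tol_ppm * 1e-6 * mz_j``; groups are the transitive
    closure of that relation, returned in ascending m/z order (size >= 2 only).
    A zero tolerance is legal and yields no groups on a strictly increasing
    m/z axis.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be non-negative")
    mz = ds.mz
    groups: list[list[int]] = []
    current = [0] if mz.size else []
    for j in range(1, mz.size):
        if mz[j] - mz[j - 1] <= tol_ppm * 1e-6 * mz[j]:
            current.append(j)
        else:
            if len(current) >= 2:
                groups.append(current)
            current = [j]
    if len(current) >= 2:
        groups.append(current)
    return groups


def _signal_mask(img: IonImage) -> np.ndarray:
    """Otsu signal mask; a degenerate (constant) image counts as zero signal."""
    try:
        return otsu_mask(img.values)
    except DegenerateImageError:
        return np.zeros(img.shape, dtype=bool)


def _oriented_regularity(values: np.ndarray, measure: str) -> float:
    try:
        return regularity(IonImage(values), measure=measure).value
    except DegenerateImageError:
        return 0.0


def evaluate_merge(
    ds: MSIDataset,
    group: list[int],
    measure: str = "scatter_ratio",
    overlap_max: float = 0.5,
    regularity_min: float = 0.05,
    regularity_slack: float = 0.05,
) -> dict:
    """Check the three merge conditions for one candidate group.

    Returns a diagnostics dict with the decision under ``merge`` and each
    sub-condition reported separately.  Degenerate member images contribute
    zero signal (overlap 0, regularity 0).

    ``regularity_min`` defaults to 0.05 — deliberately permissive: a split
    member is a randomly decimated image whose regularity falls with the
    number of split components, whereas shot-noise images score essentially
    zero (their largest connected component holds a few per cent of the
    signal pixels).  ``regularity_slack`` is subtracted from the best member
    regularity in condition (iii) to absorb binarisation noise in the
    comparison; set it to 0 for the strict inequality.
    """
    group = sorted(group)
    if len(group) < 2:
        raise MSIFilterError("merge evaluation requires a group of at least 2 peaks")
    images = [ds.ion_image(i) for i in group]
    masks = [_signal_mask(img) for img in images]

    max_overlap = 0.0
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            denom = min(masks[i].sum(), masks[j].sum())
            ov = 0.0 if denom == 0 else float((masks[i] & masks[j]).sum() / denom)
            max_overlap = max(max_overlap, ov)
    cond_overlap = max_overlap <= overlap_max

    member_reg = [_oriented_regularity(img.values, measure) for img in images]
    max_member_reg = float(max(member_reg))
    cond_regular = max_member_reg >= regularity_min

    merged_values = np.sum([img.values for img in images], axis=0)
    merged_reg = _oriented_regularity(merged_values, measure)
    cond_improves = merged_reg >= max_member_reg - regularity_slack

    return {
        "members": group,
        "member_mz": [float(ds.mz[i]) for i in group],
        "max_overlap": max_overlap,
        "member_regularity": member_reg,
        "max_member_regularity": max_member_reg,
        "merged_regularity": merged_reg,
        "cond_overlap": bool(cond_overlap),
        "cond_regularity": bool(cond_regular),
        "cond_merged_regularity": bool(cond_improves),
        "merge": bool(cond_overlap and cond_regular and cond_improves),
    }


def _merged_mz(ds: MSIDataset, group: list[int]) -> float:
    """Intensity-weighted mean m/z of the group (plain mean if all-zero)."""
    weights = ds.intensities[:, group].sum(axis=0)
    mzs = ds.mz[group]
    if weights.sum() <= 0:
        return float(mzs.mean())
    return float(np.average(mzs, weights=weights))


def apply_merge(ds: MSIDataset, plan: MergePlan) -> MSIDataset:
    """Replace each planned group by one pixel-wise-summed column.

    Total intensity is conserved exactly; the merged column takes the plan's
    m/z and the output m/z axis is re-sorted.
    """
    if not plan.groups:
        return ds.copy()
    n = ds.n_peaks
    members = [i for g in plan.groups for i in g]
    if max(members) >= n or min(members) < 0:
        raise MSIFilterError("merge plan references columns outside the dataset")
    in_group = np.zeros(n, dtype=bool)
    in_group[members] = True

    cols, mzs, ids = [], [], []
    for i in range(n):
        if not in_group[i]:
            cols.append(ds.intensities[:, i])
            mzs.append(float(ds.mz[i]))
            ids.append(ds.peak_ids[i])
    for g, mz in zip(plan.groups, plan.merged_mz):
        cols.append(ds.intensities[:, g].sum(axis=1))
        mzs.append(float(mz))
        ids.append("+".join(ds.peak_ids[i] for i in g))

    order = np.argsort(mzs, kind="stable")
    mat = np.stack(cols, axis=1)[:, order]
    return MSIDataset(
        mat, np.asarray(mzs)[order], ds.shape, [ids[i] for i in order]
    )


def split_merge(
    ds: MSIDataset,
    tol_ppm: float = 10.0,
    measure: str = "scatter_ratio",
    overlap_max: float = 0.5,
    regularity_min: float = 0.05,
    regularity_slack: float = 0.05,
    max_passes: int = 3,
) -> tuple[MSIDataset, pd.DataFrame]:
    """Full split-peak tool: find candidates, evaluate, merge accepted groups.

    Repeats until a fixed point (merged peaks can re-chain within tolerance),
    at most ``max_passes`` times.  Returns the merged dataset and a report
    table with one row per evaluated candidate group; member indices refer to
    the dataset of the pass in which the group was evaluated.
    """
    rows: list[dict] = []
    out = ds
    for pass_no in range(max_passes):
        accepted_groups, accepted_mz, pass_diags = [], [], []
        for group in find_split_candidates(out, tol_ppm):
            diag = evaluate_merge(
                out, group, measure=measure, overlap_max=overlap_max,
                regularity_min=regularity_min, regularity_slack=regularity_slack,
            )
            diag["pass"] = pass_no
            pass_diags.append(diag)
            if diag["merge"]:
                accepted_groups.append(group)
                accepted_mz.append(_merged_mz(out, group))
        rows.extend(pass_diags)
        if not accepted_groups:
            break
        out = apply_merge(out, MergePlan(accepted_groups, accepted_mz, pass_diags))
    report = pd.DataFrame(
        [
            {
                "pass": d["pass"],
                "members": ",".join(map(str, d["members"])),
                "member_mz": ",".join(f"{m:.6f}" for m in d["member_mz"]),
                "max_overlap": d["max_overlap"],
                "max_member_regularity": d["max_member_regularity"],
                "merged_regularity": d["merged_regularity"],
                "merge": d["merge"],
            }
            for d in rows
        ],
        columns=[
            "pass", "members", "member_mz", "max_overlap",
            "max_member_regularity", "merged_regularity", "merge",
        ],
    )
    return out, report
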