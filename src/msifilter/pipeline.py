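"""Configurable end-to-end filtering pipeline.

A pipeline is an ordered list of stages — ``split_merge`` (only ever first),
``reference``, ``count``, ``csr`` — applied to a peak-matched dataset; each
stage consumes the peaks that survived the previous one.  The default
profile ``maldi-default`` reproduces the reference MALDI workflow:
Spearman similarity against a 2-means tissue ROI at threshold 0, then a
count filter requiring 4 connected pixels, then a covariate-KS CSR filter
with the TIC image and Bonferroni-adjusted p-values at alpha 0.001.

The ROI and the TIC covariate are computed once, on the dataset entering the
filter stages (i.e. after split-merge when configured), so that later stages
test against a stable reference.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    MSIDataset,
    ROIMask,
    detect_roi,
    load_dataset,
    make_reference,
    save_dataset,
    tic_image,
)
from .csr import csr_select
from .errors import ConfigError, MSIFilterError
from .filters import FilterResult, all_ones_roi, count_filter, reference_filter
from .split import split_merge

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "StageRecord",
    "run_pipeline",
    "render_report",
    "MALDI_DEFAULT_STAGES",
]

logger = logging.getLogger("msifilter.pipeline")

STAGE_NAMES = ("split_merge", "reference", "count", "csr")

# Reference MALDI workflow parameters; selectable as profile "maldi-default".
MALDI_DEFAULT_STAGES = [
    {"name": "reference", "measure": "spearman", "threshold": 0.0, "reference": "roi"},
    {"name": "count", "min_pixels": 4, "aggressive": 0},
    {
        "name": "csr",
        "method": "ks_covariate",
        "covariate": "tic",
        "adjust": "bonferroni",
        "alpha": 0.001,
    },
]

PROFILES = {"maldi-default": MALDI_DEFAULT_STAGES}


@dataclass
class PipelineConfig:
    input: str | None = None
    format: str | None = None
    shape: tuple[int, int] | None = None
    roi_method: str = "kmeans"  # kmeans | otsu | all_ones | external
    roi_path: str | None = None
    reference_method: str = "sum"
    stages: list[dict] = field(default_factory=lambda: copy.deepcopy(MALDI_DEFAULT_STAGES))
    output: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        names = [s.get("name") for s in self.stages]
        for n in names:
            if n not in STAGE_NAMES:
                raise ConfigError(f"unknown stage {n!r}; valid: {STAGE_NAMES}")
        if "split_merge" in names and names.index("split_merge") != 0:
            raise ConfigError("split_merge must be the first stage")
        if names.count("split_merge") > 1:
            raise ConfigError("split_merge may appear at most once")
        if self.roi_method not in ("kmeans", "otsu", "all_ones", "external"):
            raise ConfigError(f"unknown ROI method {self.roi_method!r}")
        if self.roi_method == "external" and not self.roi_path:
            raise ConfigError("roi_method=external requires roi_path")

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                raw = (
                    json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
                )
        except (OSError, ValueError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        raw = dict(raw)
        profile = raw.pop("profile", None)
        stages = raw.pop("stages", None)
        if stages is None:
            stages = copy.deepcopy(PROFILES.get(profile or "maldi-default"))
            if stages is None:
                raise ConfigError(f"unknown profile {profile!r}")
        roi = raw.pop("roi", {}) or {}
        shape = raw.pop("shape", None)
        known = {
            "input", "format", "output", "seed", "log_level", "reference_method",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(
            stages=stages,
            shape=None if shape is None else tuple(shape),
            roi_method=roi.get("method", "kmeans"),
            roi_path=roi.get("path"),
            **raw,
        )


@dataclass
class StageRecord:
    name: str
    params: dict
    n_before: int
    n_after: int
    table: pd.DataFrame

    @property
    def n_dropped(self) -> int:
        return self.n_before - self.n_after


@dataclass
class PipelineReport:
    stages: list[StageRecord]
    n_initial: int
    n_final: int
    seed: int
    config: dict
    input_dataset: MSIDataset | None = None
    output_dataset: MSIDataset | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": i,
                    "name": s.name,
                    "peaks_in": s.n_before,
                    "peaks_out": s.n_after,
                    "dropped": s.n_dropped,
                }
                for i, s in enumerate(self.stages)
            ],
            columns=["stage", "name", "peaks_in", "peaks_out", "dropped"],
        )

    def summary_text(self) -> str:
        lines = [
            f"peaks in: {self.n_initial}",
            f"peaks out: {self.n_final}",
            f"seed: {self.seed}",
            "",
        ]
        for i, s in enumerate(self.stages):
            lines.append(
                f"stage {i} {s.name}: {s.n_before} -> {s.n_after} "
                f"(dropped {s.n_dropped}) params={json.dumps(s.params, sort_keys=True, default=str)}"
            )
        return "\n".join(lines) + "\n"


def _build_roi(cfg: PipelineConfig, ds: MSIDataset) -> ROIMask:
    if cfg.roi_method == "all_ones":
        return all_ones_roi(ds.shape)
    if cfg.roi_method == "external":
        mask = np.loadtxt(cfg.roi_path, delimiter="\t") > 0
        if mask.shape != ds.shape:
            raise ConfigError("external ROI shape does not match dataset grid")
        return ROIMask(mask, origin="external")
    if cfg.roi_method == "otsu":
        return detect_roi(ds, "otsu", reference=make_reference(ds, cfg.reference_method))
    return detect_roi(ds, "kmeans", seed=cfg.seed)


def run_pipeline(
    cfg: PipelineConfig, ds: MSIDataset | None = None
) -> tuple[MSIDataset, PipelineReport]:
    """Apply the configured stages in order; returns the filtered dataset + report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if ds is None:
        if cfg.input is None:
            raise ConfigError("no input dataset: set 'input' or pass a dataset")
        ds = load_dataset(cfg.input, format=cfg.format, shape=cfg.shape)
    initial = ds.n_peaks
    records: list[StageRecord] = []
    current = ds

    stages = list(cfg.stages)
    # split-merge (always first when present) operates on columns, not keeps
    if stages and stages[0]["name"] == "split_merge":
        params = {k: v for k, v in stages[0].items() if k != "name"}
        t0 = time.perf_counter()
        n_before = current.n_peaks
        current, merge_report = split_merge(current, **params)
        records.append(
            StageRecord("split_merge", params, n_before, current.n_peaks, merge_report)
        )
        logger.info(
            "stage split_merge: %d -> %d peaks (%.2fs)",
            n_before, current.n_peaks, time.perf_counter() - t0,
        )
        stages = stages[1:]

    roi = None
    covariate_tic = None
    if any(s["name"] in ("reference", "count", "csr") for s in stages):
        roi = _build_roi(cfg, current)
        covariate_tic = tic_image(current)

    for stage in stages:
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        n_before = current.n_peaks
        if n_before == 0:
            logger.warning("no peaks left; skipping remaining stages")
            break
        t0 = time.perf_counter()
        if name == "reference":
            ref_kind = params.pop("reference", "roi")
            ref = roi if ref_kind == "roi" else make_reference(current, ref_kind)
            result: FilterResult = reference_filter(current, ref, **params)
            params["reference"] = ref_kind
        elif name == "count":
            result = count_filter(current, roi, **params)
        elif name == "csr":
            cov_kind = params.pop("covariate", "tic")
            sum_type = cov_kind in ("tic", "sum")
            cov = covariate_tic if sum_type else make_reference(current, cov_kind)
            params.setdefault("exclude_self", sum_type)
            result = csr_select(current, covariate=cov, **params)
            params["covariate"] = cov_kind
        else:  # pragma: no cover - guarded by PipelineConfig validation
            raise ConfigError(f"stage {name!r} cannot appear here")
        table = result.to_frame(current)
        current = current.subset(result.keep)
        records.append(StageRecord(name, params, n_before, current.n_peaks, table))
        logger.info(
            "stage %s: %d -> %d peaks (%.2fs)",
            name, n_before, current.n_peaks, time.perf_counter() - t0,
        )

    report = PipelineReport(
        stages=records,
        n_initial=initial,
        n_final=current.n_peaks,
        seed=cfg.seed,
        config={
            "roi_method": cfg.roi_method,
            "reference_method": cfg.reference_method,
            "stages": cfg.stages,
            "seed": cfg.seed,
        },
        input_dataset=ds,
        output_dataset=current,
    )
    if cfg.output:
        out = Path(cfg.output)
        out.mkdir(parents=True, exist_ok=True)
        save_dataset(current, out / "filtered.imzML")
        render_report(report, out)
    return current, report


def render_report(report: PipelineReport, out_dir, gallery: bool = True) -> list[Path]:
    """Write per-stage TSVs, a plain-text summary, and an optional ion-image gallery.

    Outputs are byte-identical across runs with the same seed (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, s in enumerate(report.stages):
        p = out / f"stage_{i}_{s.name}.tsv"
        s.table.to_csv(p, sep="\t", index=False, float_format="%.8g")
        written.append(p)
    summary = out / "summary.txt"
    summary.write_text(report.summary_text())
    written.append(summary)
    stage_summary = out / "stage_counts.tsv"
    report.summary_frame().to_csv(stage_summary, sep="\t", index=False)
    written.append(stage_summary)
    if gallery and report.input_dataset is not None and report.output_dataset is not None:
        p = _render_gallery(report, out / "gallery.png")
        if p is not None:
            written.append(p)
    return written


def _render_gallery(report: PipelineReport, path: Path) -> Path | None:
    """Ion images of the five dropped and five kept peaks with the largest
    mean intensity (skipped when either side is empty)."""
    ds_in, ds_out = report.input_dataset, report.output_dataset
    kept_ids = set(ds_out.peak_ids)
    mean_int = ds_in.intensities.mean(axis=0)
    kept_idx = [i for i in range(ds_in.n_peaks) if ds_in.peak_ids[i] in kept_ids]
    dropped_idx = [i for i in range(ds_in.n_peaks) if ds_in.peak_ids[i] not in kept_ids]
    if not kept_idx or not dropped_idx:
        return None
    top = lambda idx: sorted(idx, key=lambda i: -mean_int[i])[:5]
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [("filtered", top(dropped_idx)), ("selected", top(kept_idx))]
    n_cols = max(len(r[1]) for r in rows)
    fig, axes = plt.subplots(2, n_cols, figsize=(2.2 * n_cols, 4.8), squeeze=False)
    for r, (label, idxs) in enumerate(rows):
        for c in range(n_cols):
            ax = axes[r][c]
            ax.axis("off")
            if c < len(idxs):
                img = ds_in.ion_image(idxs[c])
                ax.imshow(img.values, cmap="viridis")
                ax.set_title(f"{label}\nm/z {img.mz:.3f}", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
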