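"""Orchestration: calibrate → quantify CT → quantify histology → correlate.

Each study sample contributes a CT-derived ethanol distribution volume and a
histology-derived necrotic volume; the correlation stage reduces these to
per-sample necrosis-to-distribution ratios, per-group mean/sd, and
between-group fold-changes of the group means.  Reports are written as CSV
and JSON alongside a provenance record (input hashes, parameters, seed) so
every number is recomputable from the persisted intermediates.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .calibration import fit_two_point
from .ct_volumetrics import (
    necrosis_to_distribution_ratio,
    segment_distribution,
    to_concentration,
)
from .histology import necrotic_volume, segment_necrosis, segment_tissue

__all__ = [
    "RunConfig",
    "SampleConfig",
    "SampleMeasurement",
    "CorrelationReport",
    "StageError",
    "fold_change",
    "correlate",
    "run_pipeline",
]


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def fold_change(group_a_mean: float, group_b_mean: float) -> float:
    """Ratio of group means (A over B)."""
    if group_b_mean <= 0:
        raise ValueError("fold change undefined for non-positive denominator")
    return group_a_mean / group_b_mean


@dataclass(frozen=True)
class SampleConfig:
    sample_id: str
    group: str
    ct_path: str
    tissue_mask_path: str | None = None
    slides_dir: str | None = None
    tissue_threshold: float | None = None
    necrosis_threshold: float | None = None
    exclusions: dict = field(default_factory=dict)  # section index -> roi indices


@dataclass(frozen=True)
class RunConfig:
    hu_zero: float
    hu_hundred: float
    output_dir: str
    lower: float = 0.20
    upper: float | None = None
    pixel_size_um: float = 40.0
    step_mm: float = 1.0
    tissue_threshold: float = 0.5
    necrosis_threshold: float = 0.65
    seed: int = 0
    samples: tuple[SampleConfig, ...] = ()

    def __post_init__(self) -> None:
        if not self.lower >= 0:
            raise ValueError("lower threshold must be >= 0")
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError("upper must exceed lower")
        fit_two_point(self.hu_zero, self.hu_hundred)  # validates standards

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            cal = raw["calibration"]
            ct = raw.get("ct", {})
            hist = raw.get("histology", {})
            samples = tuple(
                SampleConfig(
                    sample_id=str(s["id"]),
                    group=str(s["group"]),
                    ct_path=s["ct"],
                    tissue_mask_path=s.get("tissue_mask"),
                    slides_dir=s.get("slides"),
                    tissue_threshold=s.get("tissue_threshold"),
                    necrosis_threshold=s.get("necrosis_threshold"),
                    exclusions={
                        int(k): list(v)
                        for k, v in (s.get("exclusions") or {}).items()
                    },
                )
                for s in raw.get("samples", [])
            )
            return cls(
                hu_zero=float(cal["hu_zero"]),
                hu_hundred=float(cal["hu_hundred"]),
                output_dir=raw.get("output_dir", "."),
                lower=float(ct.get("lower", 0.20)),
                upper=None if ct.get("upper") is None else float(ct["upper"]),
                pixel_size_um=float(hist.get("pixel_size_um", 40.0)),
                step_mm=float(hist.get("step_mm", 1.0)),
                tissue_threshold=float(hist.get("tissue_threshold", 0.5)),
                necrosis_threshold=float(hist.get("necrosis_threshold", 0.65)),
                seed=int(raw.get("seed", 0)),
                samples=samples,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise StageError("config", f"invalid run configuration: {exc}") from exc


@dataclass(frozen=True)
class SampleMeasurement:
    sample_id: str
    group: str
    distribution_volume_ul: float
    necrotic_volume_ul: float | None = None
    aspect_ratio: float = float("nan")
    n_components: int = 0

    @property
    def ratio(self) -> float:
        if self.necrotic_volume_ul is None or self.distribution_volume_ul <= 0:
            return float("nan")
        return necrosis_to_distribution_ratio(
            self.necrotic_volume_ul, self.distribution_volume_ul
        )


@dataclass(frozen=True)
class CorrelationReport:
    per_sample: pd.DataFrame
    group_stats: dict  # group -> {metric: {mean, sd, n}}
    fold_changes: dict  # "A_vs_B" -> {metric: fold}

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "group_stats": self.group_stats,
            "fold_changes": self.fold_changes,
        }


_METRICS = ("distribution_volume_ul", "necrotic_volume_ul", "ratio")


def correlate(measurements: list[SampleMeasurement]) -> CorrelationReport:
    """Reduce per-sample measurements to group statistics and fold-changes.

    The group-average ratio is the mean of per-sample ratios (not the ratio
    of group means); fold-changes are ratios of group means, reported with
    both group labels in the key.
    """
    rows = [
        {
            "sample_id": m.sample_id,
            "group": m.group,
            "distribution_volume_ul": m.distribution_volume_ul,
            "necrotic_volume_ul": m.necrotic_volume_ul,
            "aspect_ratio": m.aspect_ratio,
            "n_components": m.n_components,
            "ratio": m.ratio,
        }
        for m in measurements
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "group",
            "distribution_volume_ul",
            "necrotic_volume_ul",
            "aspect_ratio",
            "n_components",
            "ratio",
        ],
    )
    if df.empty:
        warnings.warn("no samples: empty correlation report", stacklevel=2)
        return CorrelationReport(per_sample=df, group_stats={}, fold_changes={})

    group_stats: dict = {}
    for group, sub in df.groupby("group", sort=True):
        group_stats[group] = {}
        for metric in _METRICS:
            vals = sub[metric].dropna().astype(float)
            group_stats[group][metric] = {
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
    fold_changes: dict = {}
    groups = sorted(group_stats)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            key = f"{ga}_vs_{gb}"
            fold_changes[key] = {}
            for metric in ("distribution_volume_ul", "necrotic_volume_ul"):
                a = group_stats[ga][metric]["mean"]
                b = group_stats[gb][metric]["mean"]
                if np.isfinite(a) and np.isfinite(b) and b > 0:
                    fold_changes[key][metric] = fold_change(a, b)
    return CorrelationReport(
        per_sample=df, group_stats=group_stats, fold_changes=fold_changes
    )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _quantify_ct_sample(cfg: RunConfig, sample: SampleConfig):
    try:
        ct = aio.load_ct_volume(sample.ct_path)
        tissue = (
            aio.load_mask(sample.tissue_mask_path, like=ct)
            if sample.tissue_mask_path
            else None
        )
    except aio.VolumeIOError as exc:
        raise StageError("quantify-ct", str(exc)) from exc
    model = fit_two_point(cfg.hu_zero, cfg.hu_hundred)
    conc = to_concentration(ct, model, tissue)
    return segment_distribution(conc, lower=cfg.lower, upper=cfg.upper)


def _quantify_histology_sample(cfg: RunConfig, sample: SampleConfig) -> float | None:
    if sample.slides_dir is None:
        return None
    try:
        sections = aio.load_sections(
            sample.slides_dir, cfg.pixel_size_um, cfg.step_mm
        )
    except aio.VolumeIOError as exc:
        raise StageError("quantify-histology", str(exc)) from exc
    t_thr = sample.tissue_threshold or cfg.tissue_threshold
    n_thr = sample.necrosis_threshold or cfg.necrosis_threshold
    results = []
    for sec in sections:
        tissue = segment_tissue(sec, threshold=t_thr)
        results.append(
            segment_necrosis(
                tissue.masked_image,
                tissue.mask,
                threshold=n_thr,
                pixel_size=sec.pixel_size,
                exclusions=sample.exclusions.get(sec.section_index, ()),
                step_size=sec.step_size,
            )
        )
    return necrotic_volume(results).volume_ul


def run_pipeline(config: RunConfig) -> CorrelationReport:
    """Run all stages over the configured samples and persist reports.

    Writes ``report.csv``, ``report.json`` and ``provenance.json`` under
    ``config.output_dir``.  Output files are byte-identical across reruns
    with identical config and inputs.  Any stage failure raises a
    :class:`StageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    measurements = []
    provenance: dict = {
        "seed": config.seed,
        "parameters": {
            "hu_zero": config.hu_zero,
            "hu_hundred": config.hu_hundred,
            "lower": config.lower,
            "upper": config.upper,
            "pixel_size_um": config.pixel_size_um,
            "step_mm": config.step_mm,
            "tissue_threshold": config.tissue_threshold,
            "necrosis_threshold": config.necrosis_threshold,
        },
        "inputs": {},
    }
    for sample in config.samples:
        dist = _quantify_ct_sample(config, sample)
        nec_vol = _quantify_histology_sample(config, sample)
        measurements.append(
            SampleMeasurement(
                sample_id=sample.sample_id,
                group=sample.group,
                distribution_volume_ul=dist.volume_ul,
                necrotic_volume_ul=nec_vol,
                aspect_ratio=dist.aspect_ratio,
                n_components=dist.n_components,
            )
        )
        inputs = {"ct": _sha256(sample.ct_path)}
        if sample.tissue_mask_path:
            inputs["tissue_mask"] = _sha256(sample.tissue_mask_path)
        if sample.slides_dir:
            inputs["slides"] = {
                p.name: _sha256(p)
                for p in sorted(Path(sample.slides_dir).iterdir())
                if p.suffix.lower() in aio.SLIDE_EXTENSIONS
            }
        provenance["inputs"][sample.sample_id] = inputs

    report = correlate(measurements)
    report.per_sample.to_csv(out / "report.csv", index=False)
    aio.save_json(report.to_dict(), out / "report.json")
    aio.save_json(provenance, out / "provenance.json")
    return report
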