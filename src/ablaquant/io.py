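"""File I/O: NIfTI volumes, slide images, and tabular/JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .ct_volumetrics import ConcentrationProjection, CtVolume, CumulativeVolumeCurve
from .histology import HistologySection

__all__ = [
    "load_ct_volume",
    "save_ct_volume",
    "load_mask",
    "save_mask",
    "load_sections",
    "save_curve_csv",
    "save_projection_png",
    "save_json",
]

SLIDE_EXTENSIONS = (".tif", ".tiff", ".png")


class VolumeIOError(IOError):
    """Raised when a volume file cannot be read or its header is invalid."""


def load_ct_volume(path: str | Path) -> CtVolume:
    """Read a NIfTI-1 volume; voxel spacing (mm) comes from the header zooms."""
    path = Path(path)
    try:
        img = nib.load(path)
        grid = np.asarray(img.get_fdata(), dtype=float)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    if grid.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got shape {grid.shape}")
    return CtVolume(grid=grid, spacing=tuple(float(z) for z in zooms))


def save_ct_volume(grid: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), str(path))


def load_mask(path: str | Path, like: CtVolume | None = None) -> np.ndarray:
    vol = load_ct_volume(path)
    mask = vol.grid > 0.5
    if like is not None and mask.shape != like.grid.shape:
        raise VolumeIOError(
            f"mask shape {mask.shape} does not match volume {like.grid.shape}"
        )
    return mask


def save_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    save_ct_volume(mask.astype(np.uint8), spacing, path)


def load_sections(
    directory: str | Path, pixel_size_um: float, step_mm: float
) -> list[HistologySection]:
    """Load a serial-section series (TIFF/PNG), ordered by sorted filename."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in SLIDE_EXTENSIONS
    )
    if not paths:
        raise VolumeIOError(f"no slide images (.tif/.png) in {directory}")
    sections = []
    for idx, p in enumerate(paths):
        if p.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(p)
        else:
            img = iio.imread(p)
        sections.append(
            HistologySection(
                image=np.asarray(img),
                pixel_size=pixel_size_um,
                section_index=idx,
                step_size=step_mm,
            )
        )
    return sections


def save_curve_csv(curve: CumulativeVolumeCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"threshold": curve.thresholds, "volume_uL": curve.volumes_ul}
    ).to_csv(path, index=False)


def save_projection_png(proj: ConcentrationProjection, stem: str | Path) -> None:
    """Write a 16-bit PNG of the projection and an 8-bit PNG of the banded copy.

    Concentrations are scaled so 0-120% spans the integer range; NaN (never
    evaluated) renders as 0.
    """
    stem = Path(stem)
    img = np.nan_to_num(proj.image, nan=0.0)
    iio.imwrite(
        stem.with_suffix(".png"),
        np.clip(img / 1.2 * 65535, 0, 65535).astype(np.uint16),
    )
    banded = np.nan_to_num(proj.banded, nan=0.0)
    iio.imwrite(
        stem.with_name(stem.name + "_banded.png"),
        np.clip(banded * 255, 0, 255).astype(np.uint8),
    )


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
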