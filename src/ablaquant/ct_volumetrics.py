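"""Distribution volumetrics on CT-derived ethanol concentration maps.

A post-injection CT volume is converted voxelwise to estimated ethanol
fraction with a two-point calibration; the cytotoxic distribution is the set
of evaluated tissue voxels at or above a concentration threshold (0.20 by
default, because a 10-minute exposure to 20% ethanol kills cells).  An upper
cut (1.20) can additionally exclude air-bubble artifacts whose very low
radiodensity maps to impossible concentrations; it is off by default and
intended for in-vivo-style data.

Shape is summarised by the aspect ratio

    aspect_ratio = radius_of_gyration / effective_radius
                 = (sum of voxel distances to centroid / voxel count)
                   / (3 V / 4 pi)^(1/3)

Note the numerator is the *arithmetic mean* distance to the centroid, not the
RMS radius of gyration of mechanics.  Under this convention a uniform solid
sphere scores 3R/4 / R = 0.75, not 1; the constant is exposed as
``SPHERE_ASPECT_RATIO`` so reports can be renormalised against the spherical
reference if desired.  Lower values indicate a more localized, compact
distribution; leaky, irregular distributions score higher.

All distances and centroids use voxel-center physical coordinates (mm);
anisotropic spacing is supported.  Volumes are reported in µL (= mm³).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .calibration import CalibrationModel, estimate_concentration

__all__ = [
    "CtVolume",
    "ConcentrationVolume",
    "DistributionResult",
    "CumulativeVolumeCurve",
    "ConcentrationProjection",
    "SPHERE_ASPECT_RATIO",
    "to_concentration",
    "segment_distribution",
    "cumulative_volume_curve",
    "average_curves",
    "max_concentration_projection",
    "necrosis_to_distribution_ratio",
]

#: Aspect ratio of a uniform solid sphere under the mean-distance convention.
SPHERE_ASPECT_RATIO = 0.75


@dataclass(frozen=True)
class CtVolume:
    """3D radiodensity grid (HU) with per-axis voxel spacing in mm.

    Axis order is (transverse-slice, row, column).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3 or grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", sp)

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL (1 mm³ = 1 µL)."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ConcentrationVolume:
    """Voxelwise estimated ethanol fraction; NaN marks not-evaluated voxels."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    model: CalibrationModel | None = None

    @property
    def voxel_volume_ul(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def evaluated(self) -> np.ndarray:
        return np.isfinite(self.grid)


@dataclass(frozen=True)
class DistributionResult:
    """Thresholded cytotoxic distribution and its volume/shape metrics."""

    mask: np.ndarray = field(repr=False)
    volume_ul: float
    centroid_mm: tuple[float, float, float] | None
    radius_of_gyration_mm: float
    effective_radius_mm: float
    aspect_ratio: float
    n_components: int


@dataclass(frozen=True)
class CumulativeVolumeCurve:
    """Tissue volume (µL) at or above each concentration threshold."""

    thresholds: np.ndarray
    volumes_ul: np.ndarray

    def volume_at(self, threshold: float) -> float:
        """Curve value at the grid point closest to ``threshold``."""
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.volumes_ul[idx])


@dataclass(frozen=True)
class ConcentrationProjection:
    """Maximum concentration projection along one axis, plus a banded copy."""

    image: np.ndarray
    axis: int
    banded: np.ndarray


def to_concentration(
    ct: CtVolume, model: CalibrationModel, tissue: np.ndarray | None = None
) -> ConcentrationVolume:
    """Apply the two-point calibration voxelwise.

    When quantifying tissue, ``model.hu_zero`` should be the mean pre-ablation
    tissue radiodensity (tissue is slightly more radiodense than water).
    Voxels outside ``tissue`` are set to NaN ("not evaluated") and never enter
    downstream volumes, curves or projections.
    """
    conc = estimate_concentration(ct.grid, model)
    if tissue is not None:
        tissue = np.asarray(tissue, dtype=bool)
        if tissue.shape != ct.grid.shape:
            raise ValueError(
                f"tissue mask shape {tissue.shape} != volume shape {ct.grid.shape}"
            )
        conc = np.where(tissue, conc, np.nan)
    return ConcentrationVolume(grid=conc, spacing=ct.spacing, model=model)


def segment_distribution(
    conc: ConcentrationVolume,
    lower: float = 0.20,
    upper: float | None = None,
    tissue: np.ndarray | None = None,
) -> DistributionResult:
    """Segment the cytotoxic distribution and compute its shape metrics.

    The mask keeps *all* evaluated voxels with ``lower <= c`` (and ``c <=
    upper`` when given), including disconnected components — in vivo, pure
    ethanol often produces multiple small non-contiguous distributions and
    they all count toward the volume.  Metrics are unweighted by
    concentration.  An empty mask yields volume 0 and NaN aspect ratio with a
    warning, never an exception.
    """
    if lower < 0:
        raise ValueError("lower threshold must be >= 0")
    if upper is not None and upper <= lower:
        raise ValueError("upper must exceed lower")
    grid = conc.grid
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(grid) & (grid >= lower)
        if upper is not None:
            mask &= grid <= upper
    if tissue is not None:
        mask &= np.asarray(tissue, dtype=bool)

    n_voxels = int(mask.sum())
    voxvol = conc.voxel_volume_ul
    volume = n_voxels * voxvol
    if n_voxels == 0:
        warnings.warn("empty distribution: no voxel meets the threshold", stacklevel=2)
        return DistributionResult(
            mask=mask,
            volume_ul=0.0,
            centroid_mm=None,
            radius_of_gyration_mm=float("nan"),
            effective_radius_mm=float("nan"),
            aspect_ratio=float("nan"),
            n_components=0,
        )

    spacing = np.asarray(conc.spacing)
    coords = np.argwhere(mask) * spacing  # voxel centers, mm
    centroid = coords.mean(axis=0)
    rg = float(np.linalg.norm(coords - centroid, axis=1).mean())
    r_eff = float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
    n_comp = int(measure.label(mask, connectivity=3).max())
    return DistributionResult(
        mask=mask,
        volume_ul=float(volume),
        centroid_mm=tuple(float(c) for c in centroid),
        radius_of_gyration_mm=rg,
        effective_radius_mm=r_eff,
        aspect_ratio=rg / r_eff,
        n_components=n_comp,
    )


def cumulative_volume_curve(
    conc: ConcentrationVolume,
    tissue: np.ndarray | None = None,
    step: float = 0.01,
) -> CumulativeVolumeCurve:
    """Cumulative volume histogram: µL of tissue at or above each threshold.

    The threshold grid spans 0 to max(1.2, observed maximum) in ``step``
    increments, covering the >100% tail produced by air-bubble artifacts.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    grid = conc.grid
    evaluated = np.isfinite(grid)
    if tissue is not None:
        evaluated &= np.asarray(tissue, dtype=bool)
    vals = grid[evaluated]
    obs_max = float(vals.max()) if vals.size else 0.0
    top = max(1.2, obs_max)
    n_steps = int(np.ceil(top / step - 1e-9))
    thresholds = np.round(np.arange(n_steps + 1) * step, 12)
    # vectorised count of vals >= t for every grid point
    order = np.sort(vals)
    counts = vals.size - np.searchsorted(order, thresholds, side="left")
    return CumulativeVolumeCurve(
        thresholds=thresholds,
        volumes_ul=counts.astype(float) * conc.voxel_volume_ul,
    )


def average_curves(curves: Sequence[CumulativeVolumeCurve]) -> CumulativeVolumeCurve:
    """Pointwise mean of cumulative volume curves sharing one threshold grid."""
    if not curves:
        raise ValueError("need >= 1 curve")
    ref = curves[0].thresholds
    for c in curves[1:]:
        if c.thresholds.shape != ref.shape or not np.allclose(c.thresholds, ref):
            raise ValueError("curves have mismatched threshold grids")
    mean = np.mean([c.volumes_ul for c in curves], axis=0)
    return CumulativeVolumeCurve(thresholds=ref.copy(), volumes_ul=mean)


def max_concentration_projection(
    conc: ConcentrationVolume, axis: int, band: float = 0.20
) -> ConcentrationProjection:
    """Project the highest estimated concentration along ``axis`` onto 2D.

    ``banded`` quantizes the image to ``band``-wide concentration bands
    (floored, clipped to [0, 1]) for display, emulating 20%-band grayscale
    figures.  Pixels with no evaluated voxel along the ray are NaN.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rays
        image = np.nanmax(conc.grid, axis=axis)
    banded = np.clip(np.floor(image / band) * band, 0.0, 1.0)
    banded = np.where(np.isfinite(image), banded, np.nan)
    return ConcentrationProjection(image=image, axis=axis, banded=banded)


def necrosis_to_distribution_ratio(
    necrotic_volume_ul: float, distribution_volume_ul: float
) -> float:
    """Ratio of pathologic necrotic volume to CT distribution volume.

    A ratio near 1 means the imaging-derived distribution predicts the
    ablative extent.  Group averages should be means of per-sample ratios,
    not ratios of group means.
    """
    if distribution_volume_ul <= 0:
        raise ValueError("distribution volume must be > 0 for a defined ratio")
    return necrotic_volume_ul / distribution_volume_ul
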