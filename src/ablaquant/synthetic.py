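"""Synthetic phantoms for the calibration, CT and histology stages.

No public image data accompanies the ablation workflow, so every stage is
exercised on generated fixtures that carry analytic ground truth:

* **Vial sets** — homogeneous ethanol--water mixtures with Gaussian
  radiodensity noise.  Defaults reproduce the observed water/ethanol summary
  radiodensities (−66.5 ± 20.3 HU and −340.3 ± 29.1 HU) and give the
  intermediate concentrations a positive radiodensity bias, emulating the
  mild non-linearity of real mixtures (mean two-point calibration error of
  about 7.7 concentration points).
* **Injection phantoms** — a tissue block submerged in buffer with embedded
  ellipsoidal (optionally multi-lobed) ethanol inclusions of known
  concentration, plus optional confounders: air bubbles (≈ −1000 HU, which
  map to impossible concentrations > 120%) and naturally-low-radiodensity
  pockets that mimic untreated tissue features below the cytotoxic
  threshold.
* **Slide series** — serial cross-sections of a necrotic ellipsoid rendered
  as an unstained gray region inside blue-textured viable tissue on a flat
  background, with the analytic cross-section area of every plane recorded.

Noise is i.i.d. Gaussian per voxel (no spatial correlation) — a declared
simplification, as only mean/sd summaries of real scans are available.
Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import RadiodensitySample
from .ct_volumetrics import CtVolume
from .histology import HistologySection

__all__ = [
    "VialSpec",
    "Inclusion",
    "AirBubble",
    "LowDensityPocket",
    "InjectionPhantomSpec",
    "SlideSeriesSpec",
    "SyntheticTruth",
    "default_vial_specs",
    "make_vials",
    "make_injection_phantom",
    "make_slide_series",
    "WATER_HU",
    "ETHANOL_HU",
    "TISSUE_HU",
    "AIR_HU",
]

WATER_HU = -66.5
ETHANOL_HU = -340.3
TISSUE_HU = 60.0  # tissue is slightly more radiodense than water
AIR_HU = -1000.0


class SpecError(ValueError):
    """Raised when a generator spec is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record carried alongside every generated fixture."""

    params: dict = field(default_factory=dict)
    true_volume_ul: float | None = None  # analytic inclusion/solid volume
    rasterized_volume_ul: float | None = None
    per_slide_area_cm2: np.ndarray | None = None
    true_necrotic_volume_ul: float | None = None

    def to_dict(self) -> dict:
        d = dict(self.params)
        for key in (
            "true_volume_ul",
            "rasterized_volume_ul",
            "true_necrotic_volume_ul",
        ):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        if self.per_slide_area_cm2 is not None:
            d["per_slide_area_cm2"] = [float(a) for a in self.per_slide_area_cm2]
        return d


# --------------------------------------------------------------------------
# vials


@dataclass(frozen=True)
class VialSpec:
    """One homogeneous ethanol--water vial: truth, HU mean/sd, voxel count."""

    true_concentration: float
    mean_hu: float
    sd_hu: float
    n_voxels: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise SpecError("sd_hu must be >= 0")
        if self.n_voxels < 1:
            raise SpecError("n_voxels must be >= 1")


# Positive HU bias at intermediate concentrations, expressed in concentration
# points of the (-66.5, -340.3) calibration range: mean 7.7, sd ~6.6 points.
_DEFAULT_BIAS_POINTS = {0.25: 2.0, 0.50: 6.2, 0.75: 14.9}
# Per-level radiodensity spread; the five-level mean is 20.8 HU.
_DEFAULT_SD_HU = {0.0: 20.3, 0.25: 18.0, 0.50: 15.0, 0.75: 21.6, 1.0: 29.1}


def default_vial_specs(
    n_replicates: int = 20, n_voxels: int = 2000
) -> list[VialSpec]:
    """The standard vial panel: 0/25/50/75/100% ethanol, ``n_replicates`` each.

    Endpoint means are the water/ethanol reference radiodensities; the
    intermediates sit above the two-point line by a fixed positive bias.
    """
    hu_range = ETHANOL_HU - WATER_HU
    specs = []
    for conc in (0.0, 0.25, 0.50, 0.75, 1.0):
        bias_hu = -_DEFAULT_BIAS_POINTS.get(conc, 0.0) / 100.0 * hu_range
        mean = WATER_HU + conc * hu_range + bias_hu
        for rep in range(n_replicates):
            specs.append(
                VialSpec(
                    true_concentration=conc,
                    mean_hu=mean,
                    sd_hu=_DEFAULT_SD_HU[conc],
                    n_voxels=n_voxels,
                    label=f"vial_c{int(round(conc * 100))}_{rep}",
                )
            )
    return specs


def make_vials(
    specs: Sequence[VialSpec] | None = None, seed: int = 0
) -> tuple[list[RadiodensitySample], SyntheticTruth]:
    """Draw Gaussian radiodensity readings for every vial spec."""
    if specs is None:
        specs = default_vial_specs()
    rng = np.random.default_rng(seed)
    samples = [
        RadiodensitySample(
            label=spec.label or f"vial{i}",
            true_concentration=spec.true_concentration,
            values=rng.normal(spec.mean_hu, spec.sd_hu, size=spec.n_voxels),
        )
        for i, spec in enumerate(specs)
    ]
    truth = SyntheticTruth(
        params={
            "seed": seed,
            "vials": [
                {
                    "label": s.label,
                    "true_concentration": s.true_concentration,
                    "mean_hu": s.mean_hu,
                    "sd_hu": s.sd_hu,
                    "n_voxels": s.n_voxels,
                }
                for s in specs
            ],
        }
    )
    return samples, truth


# --------------------------------------------------------------------------
# injection phantoms


@dataclass(frozen=True)
class Inclusion:
    """Ellipsoidal injected-ethanol region inside the tissue block."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    concentration: float = 0.6
    profile: str = "uniform"  # or "radial-decay": c falls linearly to 0 at edge

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise SpecError("inclusion radii must be > 0")
        if self.profile not in ("uniform", "radial-decay"):
            raise SpecError(f"unknown concentration profile {self.profile!r}")

    @property
    def analytic_volume_ul(self) -> float:
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class AirBubble:
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class LowDensityPocket:
    """Naturally-low-radiodensity tissue feature (HU between buffer and tissue)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    hu: float = 25.0


@dataclass(frozen=True)
class InjectionPhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    tissue_hu: tuple[float, float] = (TISSUE_HU, 0.0)  # mean, sd
    buffer_hu: tuple[float, float] = (0.0, 0.0)
    ethanol_hu: float = ETHANOL_HU  # HU of the 100% standard
    inclusions: tuple[Inclusion, ...] = ()
    air_bubbles: tuple[AirBubble, ...] = ()
    pockets: tuple[LowDensityPocket, ...] = ()
    seed: int = 0


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: Sequence[float],
    radii_mm: Sequence[float],
) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    d2 = sum(
        ((g - c) / r) ** 2 for g, c, r in zip((zz, yy, xx), center_mm, radii_mm)
    )
    return d2 <= 1.0


def make_injection_phantom(
    spec: InjectionPhantomSpec,
) -> tuple[CtVolume, np.ndarray, SyntheticTruth]:
    """Render a tissue-in-buffer CT phantom with known ethanol inclusions.

    The tissue region is a centered ellipsoid spanning 90% of the grid
    extent; everything outside is buffer.  Inclusion voxels are set to
    ``hu_tissue + c · (hu_ethanol − hu_tissue)`` (plus noise), i.e. exactly
    what the two-point calibration with the tissue baseline as 0% standard
    will invert.  Both the analytic ellipsoid volume and the volume of the
    rasterized truth mask are recorded.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]
    tissue = _ellipsoid_mask(shape, spacing, center, [0.45 * e for e in extent])

    tissue_mean, tissue_sd = spec.tissue_hu
    buffer_mean, buffer_sd = spec.buffer_hu
    grid = np.full(shape, buffer_mean)
    if buffer_sd > 0:
        grid = grid + rng.normal(0, buffer_sd, shape)
    tissue_field = np.full(shape, tissue_mean)
    if tissue_sd > 0:
        tissue_field = tissue_field + rng.normal(0, tissue_sd, shape)
    grid = np.where(tissue, tissue_field, grid)

    voxvol = float(np.prod(spacing))
    hu_span = spec.ethanol_hu - tissue_mean
    truth_mask = np.zeros(shape, dtype=bool)
    analytic = 0.0
    for inc in spec.inclusions:
        mask = _ellipsoid_mask(shape, spacing, inc.center_mm, inc.radii_mm)
        if np.any(mask & ~tissue):
            raise SpecError(f"inclusion at {inc.center_mm} extends outside tissue")
        if inc.profile == "uniform":
            conc = np.full(shape, inc.concentration)
        else:  # radial-decay: peak at center, 0 at the ellipsoid surface
            coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
            zz, yy, xx = np.meshgrid(*coords, indexing="ij")
            d = np.sqrt(
                sum(
                    ((g - c) / r) ** 2
                    for g, c, r in zip((zz, yy, xx), inc.center_mm, inc.radii_mm)
                )
            )
            conc = inc.concentration * np.clip(1.0 - d, 0.0, 1.0)
        grid = np.where(mask, tissue_mean + conc * hu_span, grid)
        if tissue_sd > 0:
            grid = np.where(mask, grid + rng.normal(0, tissue_sd, shape), grid)
        truth_mask |= mask
        analytic += inc.analytic_volume_ul

    for bubble in spec.air_bubbles:
        mask = _ellipsoid_mask(
            shape, spacing, bubble.center_mm, [bubble.radius_mm] * 3
        )
        grid = np.where(mask, AIR_HU, grid)
    for pocket in spec.pockets:
        mask = _ellipsoid_mask(
            shape, spacing, pocket.center_mm, [pocket.radius_mm] * 3
        )
        grid = np.where(mask & tissue & ~truth_mask, pocket.hu, grid)

    truth = SyntheticTruth(
        params={
            "seed": spec.seed,
            "grid_shape": list(shape),
            "spacing": list(spacing),
            "tissue_hu": list(spec.tissue_hu),
            "ethanol_hu": spec.ethanol_hu,
            "n_inclusions": len(spec.inclusions),
        },
        true_volume_ul=analytic,
        rasterized_volume_ul=float(truth_mask.sum()) * voxvol,
    )
    return CtVolume(grid=grid, spacing=spacing), tissue, truth


# --------------------------------------------------------------------------
# slide series


@dataclass(frozen=True)
class SlideSeriesSpec:
    """Serial sections through a necrotic ellipsoid in viable liver.

    The viable tissue is rendered blue-dominant with multiplicative speckle
    (the entropy-based tissue mask needs texture); the necrotic core is
    unstained gray with weaker speckle; the slide background is flat.
    """

    necrotic_radii_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    step_mm: float = 1.0
    # 25 µm/px keeps the fixed pixel-count rules (5000 px minimum region)
    # small relative to real cross-sections, as they are on 10x scans
    pixel_size_um: float = 25.0
    image_shape: tuple[int, int] = (512, 512)
    tissue_radius_mm: float = 4.5
    viable_rgb: tuple[int, int, int] = (70, 85, 200)
    necrotic_rgb: tuple[int, int, int] = (165, 160, 140)
    background_rgb: tuple[int, int, int] = (245, 245, 245)
    speckle_sd: float = 0.10  # multiplicative, viable tissue
    necrotic_speckle_sd: float = 0.04
    vessel_count: int = 0
    vessel_radius_mm: float = 0.25
    margin_sections: int = 1  # blank sections beyond each pole
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0 or self.pixel_size_um <= 0:
            raise SpecError("step_mm and pixel_size_um must be > 0")
        if any(r <= 0 for r in self.necrotic_radii_mm):
            raise SpecError("necrotic radii must be > 0")


def make_slide_series(
    spec: SlideSeriesSpec,
) -> tuple[list[HistologySection], SyntheticTruth]:
    """Render the stained serial-section series and its analytic truth.

    Sections are sampled every ``step_mm`` along the first ellipsoid axis,
    symmetric about the mid-plane (which is always sampled).  The in-plane
    cross-section at offset z is an ellipse with semi-axes
    ``b·sqrt(1−(z/a)²)``, ``c·sqrt(1−(z/a)²)``; its analytic area π·b'·c' is
    recorded per slide in cm².
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.necrotic_radii_mm
    n_half = int(np.floor(a / spec.step_mm)) + spec.margin_sections
    offsets = np.arange(-n_half, n_half + 1) * spec.step_mm

    h, w = spec.image_shape
    px_mm = spec.pixel_size_um / 1000.0
    yy, xx = np.meshgrid(
        (np.arange(h) - h / 2) * px_mm, (np.arange(w) - w / 2) * px_mm, indexing="ij"
    )
    tissue_mask = yy**2 + xx**2 <= spec.tissue_radius_mm**2

    sections: list[HistologySection] = []
    true_areas = []
    for idx, z in enumerate(offsets):
        frac = 1.0 - (z / a) ** 2
        if frac > 0:
            bz, cz = b * np.sqrt(frac), c * np.sqrt(frac)
            necrotic = (yy / bz) ** 2 + (xx / cz) ** 2 <= 1.0
            true_area_cm2 = np.pi * bz * cz / 100.0  # mm² -> cm²
        else:
            necrotic = np.zeros((h, w), dtype=bool)
            true_area_cm2 = 0.0

        img = np.empty((h, w, 3), dtype=float)
        img[:] = spec.background_rgb
        speckle = 1.0 + rng.normal(0, spec.speckle_sd, (h, w, 3))
        img[tissue_mask] = (np.array(spec.viable_rgb) * speckle)[tissue_mask]
        nec_speckle = 1.0 + rng.normal(0, spec.necrotic_speckle_sd, (h, w, 3))
        nec_px = tissue_mask & necrotic
        img[nec_px] = (np.array(spec.necrotic_rgb) * nec_speckle)[nec_px]

        for _ in range(spec.vessel_count):
            # gray vessel lumen in viable tissue, caught by the same low-blue
            # threshold as necrosis; placed away from the necrotic core
            theta = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.6, 0.85) * spec.tissue_radius_mm
            vy, vx = rad * np.sin(theta), rad * np.cos(theta)
            vessel = (yy - vy) ** 2 + (xx - vx) ** 2 <= spec.vessel_radius_mm**2
            img[vessel & tissue_mask & ~necrotic] = spec.necrotic_rgb

        sections.append(
            HistologySection(
                image=np.clip(img, 0, 255).astype(np.uint8),
                pixel_size=spec.pixel_size_um,
                section_index=idx,
                step_size=spec.step_mm,
            )
        )
        true_areas.append(true_area_cm2)

    areas = np.array(true_areas)
    truth = SyntheticTruth(
        params={
            "seed": spec.seed,
            "necrotic_radii_mm": list(spec.necrotic_radii_mm),
            "step_mm": spec.step_mm,
            "pixel_size_um": spec.pixel_size_um,
            "n_sections": len(sections),
        },
        true_volume_ul=4.0 / 3.0 * np.pi * a * b * c,
        true_necrotic_volume_ul=4.0 / 3.0 * np.pi * a * b * c,
        per_slide_area_cm2=areas,
    )
    return sections, truth
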