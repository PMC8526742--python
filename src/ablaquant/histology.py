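"""Semi-automated necrotic-area segmentation of viability-stained sections.

NADH-diaphorase stains viable tissue blue and leaves non-viable (necrotic)
tissue unstained, so on an RGB scan of a stained section the necrotic zone is
the low-blue region inside the tissue.  Quantification is a two-stage
pipeline:

1. **Tissue segmentation** — a local-entropy filter on the blue channel
   separates textured tissue from the flat slide background.  The entropy
   image is binarized at a user-defined threshold, small components are
   deleted, and the mask is cleaned by erode → fill-holes → dilate with a
   flat structuring element.  The fill-holes step is what recovers necrotic
   zones whose weak texture would otherwise punch holes in the tissue mask.
2. **Necrosis segmentation** — the blue channel of the tissue-masked image is
   binarized (necrosis = blue *below* the threshold), components smaller than
   5000 px are removed, only the five largest regions are retained, and
   user-flagged regions (e.g. large vasculature caught by the same threshold)
   are excluded.

Areas are reported in cm²; a serial-section series reduces to a necrotic
volume in µL by summing area × step size over sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters.rank import entropy as rank_entropy

__all__ = [
    "HistologySection",
    "TissueSegmentation",
    "NecrosisRegion",
    "NecrosisResult",
    "NecrosisVolume",
    "ManualComparison",
    "segment_tissue",
    "segment_necrosis",
    "necrotic_volume",
    "compare_to_manual",
    "pixel_area_cm2",
]

UM2_PER_CM2 = 1e8


def pixel_area_cm2(pixel_size_um: float) -> float:
    """Area of one pixel in cm² given its edge length in µm."""
    return pixel_size_um**2 / UM2_PER_CM2


@dataclass(frozen=True)
class HistologySection:
    """One RGB scan of a stained serial section.

    ``pixel_size`` is µm per pixel; ``step_size`` is the mm between sampled
    section planes (sections may be cut thinner but only every ``step_size``
    is quantified).
    """

    image: np.ndarray
    pixel_size: float  # µm / px
    section_index: int = 0
    step_size: float = 1.0  # mm

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] < 3:
            raise ValueError("image must be H x W x RGB")
        if self.pixel_size <= 0 or self.step_size <= 0:
            raise ValueError("pixel_size and step_size must be > 0")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class TissueSegmentation:
    mask: np.ndarray = field(repr=False)
    tissue_area_cm2: float
    boundaries: list = field(repr=False)
    masked_image: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class NecrosisRegion:
    mask: np.ndarray = field(repr=False)
    area_cm2: float
    boundary: np.ndarray = field(repr=False)
    n_pixels: int


@dataclass(frozen=True)
class NecrosisResult:
    """Retained necrotic regions of one section (at most five)."""

    rois: list  # of NecrosisRegion
    excluded: list  # NecrosisRegion flagged by the user (e.g. vasculature)
    necrotic_area_cm2: float
    step_size: float = 1.0  # mm, carried for volume reconstruction


@dataclass(frozen=True)
class NecrosisVolume:
    per_section_areas_cm2: np.ndarray
    volume_ul: float


@dataclass(frozen=True)
class ManualComparison:
    mean_signed_difference_cm2: float  # auto - manual
    mean_absolute_difference_cm2: float


def _blue_channel_u8(image: np.ndarray) -> np.ndarray:
    blue = image[..., 2]
    if blue.dtype == np.uint8:
        return blue
    blue = np.asarray(blue, dtype=float)
    if blue.max() <= 1.0:
        blue = blue * 255.0
    return np.clip(blue, 0, 255).astype(np.uint8)


def _structuring_element(radius: int, shape: str) -> np.ndarray:
    if shape == "disk":
        return morphology.disk(radius)
    if shape == "square":
        return morphology.footprint_rectangle((2 * radius + 1, 2 * radius + 1))
    raise ValueError(f"unknown structuring element shape {shape!r}")


def segment_tissue(
    section: HistologySection,
    threshold: float,
    entropy_window: int = 9,
    min_region: int = 15000,
    erode_dilate_radius: int = 15,
    element: str = "disk",
) -> TissueSegmentation:
    """Segment tissue from slide background via blue-channel local entropy.

    Pipeline order (fixed): entropy filter → binarize at ``threshold`` →
    delete components < ``min_region`` px → erode → fill holes → dilate →
    boundaries and area.  The entropy image is normalized by its theoretical
    maximum log2(window²) so ``threshold`` lies in (0, 1) with stable
    semantics across slides; a texture-free (blank) image has zero entropy
    everywhere and yields an empty mask.

    Returns the mask, its area in cm², closed boundary outlines, and a copy
    of the section image with background pixels removed for the necrosis
    stage.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if entropy_window % 2 != 1 or entropy_window < 3:
        raise ValueError("entropy_window must be an odd integer >= 3")
    blue = _blue_channel_u8(section.image)
    footprint = morphology.footprint_rectangle((entropy_window, entropy_window))
    ent = rank_entropy(blue, footprint)
    ent_norm = ent / np.log2(entropy_window**2)

    mask = ent_norm >= threshold
    # max_size=n-1 keeps components of >= n pixels (the stated rule)
    mask = morphology.remove_small_objects(mask, max_size=min_region - 1, connectivity=2)
    selem = _structuring_element(erode_dilate_radius, element)
    mask = morphology.erosion(mask, selem)
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.dilation(mask, selem)

    if not mask.any():
        warnings.warn("no tissue region survived segmentation", stacklevel=2)
        boundaries: list = []
    else:
        boundaries = measure.find_contours(mask.astype(float), 0.5)
    area = float(mask.sum()) * pixel_area_cm2(section.pixel_size)
    masked = section.image.copy()
    masked[~mask] = 0
    return TissueSegmentation(
        mask=mask, tissue_area_cm2=area, boundaries=boundaries, masked_image=masked
    )


def segment_necrosis(
    masked_image: np.ndarray,
    tissue_mask: np.ndarray,
    threshold: float,
    pixel_size: float,
    min_region: int = 5000,
    keep_largest: int = 5,
    exclusions: Sequence[int] = (),
    step_size: float = 1.0,
) -> NecrosisResult:
    """Segment unstained (necrotic) regions within the tissue mask.

    Necrotic pixels are those whose normalized blue channel falls *below*
    ``threshold`` (the viability stain colors live tissue blue).  Components
    smaller than ``min_region`` px are removed; of the survivors only the
    ``keep_largest`` largest (by pixel count) are retained, then regions
    whose index (0-based, largest first) appears in ``exclusions`` — e.g.
    large vasculature — are dropped from the area total but reported.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    blue = _blue_channel_u8(masked_image).astype(float) / 255.0
    candidate = tissue_mask & (blue < threshold)
    candidate = morphology.remove_small_objects(
        candidate, max_size=min_region - 1, connectivity=2
    )
    labels = measure.label(candidate, connectivity=2)
    props = sorted(
        measure.regionprops(labels), key=lambda p: p.num_pixels, reverse=True
    )[:keep_largest]

    px_area = pixel_area_cm2(pixel_size)
    rois: list[NecrosisRegion] = []
    excluded: list[NecrosisRegion] = []
    for rank, prop in enumerate(props):
        region_mask = labels == prop.label
        contours = measure.find_contours(region_mask.astype(float), 0.5)
        boundary = max(contours, key=len) if contours else np.empty((0, 2))
        region = NecrosisRegion(
            mask=region_mask,
            area_cm2=prop.num_pixels * px_area,
            boundary=boundary,
            n_pixels=int(prop.num_pixels),
        )
        (excluded if rank in exclusions else rois).append(region)
    total = float(sum(r.area_cm2 for r in rois))
    return NecrosisResult(
        rois=rois, excluded=excluded, necrotic_area_cm2=total, step_size=step_size
    )


def necrotic_volume(series: Sequence[NecrosisResult]) -> NecrosisVolume:
    """Reconstruct necrotic volume (µL) from a serial-section series.

    volume = Σ area_i · step, with cm²·mm converted to µL (×100).  All
    sections must share one step size.
    """
    if not series:
        return NecrosisVolume(per_section_areas_cm2=np.array([]), volume_ul=0.0)
    steps = {r.step_size for r in series}
    if len(steps) > 1:
        raise ValueError(f"inconsistent step sizes {sorted(steps)}")
    step_mm = steps.pop()
    areas = np.array([r.necrotic_area_cm2 for r in series])
    return NecrosisVolume(
        per_section_areas_cm2=areas,
        volume_ul=float(areas.sum() * step_mm * 100.0),
    )


def compare_to_manual(
    auto_areas_cm2: Sequence[float], manual_areas_cm2: Sequence[float]
) -> ManualComparison:
    """Paired comparison of automated vs gold-standard manual areas.

    Reports the mean signed difference (auto − manual; positive means the
    algorithm over-segments) and the mean absolute per-pair difference.
    """
    auto = np.asarray(auto_areas_cm2, dtype=float)
    manual = np.asarray(manual_areas_cm2, dtype=float)
    if auto.shape != manual.shape:
        raise ValueError(
            f"paired sequences differ in length ({auto.size} vs {manual.size})"
        )
    diff = auto - manual
    return ManualComparison(
        mean_signed_difference_cm2=float(diff.mean()),
        mean_absolute_difference_cm2=float(np.abs(diff).mean()),
    )
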