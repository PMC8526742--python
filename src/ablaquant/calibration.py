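"""Radiodensity-to-ethanol-concentration calibration.

Ethanol attenuates X-rays less than water, so the mean radiodensity of an
ethanol--water mixture decreases approximately linearly with ethanol volume
fraction.  A two-point calibration maps Hounsfield units (HU) to estimated
ethanol concentration::

    c(HU) = (HU - HU_0%) / (HU_100% - HU_0%)

where ``HU_0%`` is the radiodensity of the 0% ethanol standard (water, or the
mean pre-ablation tissue radiodensity when quantifying tissue) and ``HU_100%``
that of pure ethanol.  Concentrations are handled as dimensionless fractions
throughout; multiply by 100 only when formatting for display.

Two error components of the calibration are quantified: the systematic error
introduced by residual non-linearity at intermediate concentrations, and the
random measurement error, i.e. the spread of the radiodensity distribution
within a homogeneous sample, expressed both in HU and as a percentage of the
calibration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RadiodensitySample",
    "CalibrationModel",
    "LinearFitResult",
    "CalibrationErrorReport",
    "SampleSummary",
    "summarize_sample",
    "fit_two_point",
    "estimate_concentration",
    "fit_linear",
    "nonlinearity_error",
    "measurement_variance",
    "error_report",
]


class CalibrationError(ValueError):
    """Raised for degenerate or invalid calibration inputs."""


@dataclass(frozen=True)
class RadiodensitySample:
    """Radiodensity readings (HU) from one segmented region of interest.

    Parameters
    ----------
    label
        Free-text identifier (e.g. vial name).
    true_concentration
        Known ethanol volume fraction in [0, 1], or ``None`` when unknown.
    values
        One or more radiodensity readings from the region, in HU.
    """

    label: str
    true_concentration: float | None
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size == 0:
            raise CalibrationError(f"sample {self.label!r} has no readings")
        if not np.all(np.isfinite(vals)):
            raise CalibrationError(f"sample {self.label!r} has non-finite readings")
        if self.true_concentration is not None and not (
            0.0 <= self.true_concentration <= 1.0
        ):
            raise CalibrationError(
                f"true_concentration {self.true_concentration} outside [0, 1]"
            )
        object.__setattr__(self, "values", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # sample sd (n-1); a single reading has zero spread by convention
        if self.values.size < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class CalibrationModel:
    """Two-point HU -> concentration map defined by the 0% and 100% standards."""

    hu_zero: float
    hu_hundred: float

    def __post_init__(self) -> None:
        if self.hu_zero == self.hu_hundred:
            raise CalibrationError(
                "degenerate calibration: 0% and 100% standards are equal "
                f"({self.hu_zero} HU)"
            )
        if self.hu_hundred > self.hu_zero:
            raise CalibrationError(
                "100% ethanol standard must be less radiodense than the 0% standard "
                f"(got hu_zero={self.hu_zero}, hu_hundred={self.hu_hundred})"
            )

    @property
    def hu_range(self) -> float:
        """Absolute radiodensity range |HU_0% - HU_100%| spanned by 0-100% ethanol."""
        return abs(self.hu_zero - self.hu_hundred)


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary least-squares fit of mean radiodensity on known concentration."""

    slope: float  # HU per concentration fraction
    intercept: float  # HU
    r_squared: float


@dataclass(frozen=True)
class CalibrationErrorReport:
    """Systematic (non-linearity) and random (variance) calibration error."""

    nonlinearity_error_mean: float  # concentration percentage points
    nonlinearity_error_sd: float
    variance_hu_mean: float  # HU
    variance_hu_sd: float
    variance_pct_of_range: float  # percent of the calibration HU range


@dataclass(frozen=True)
class SampleSummary:
    mean: float
    sd: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)


def summarize_sample(
    sample: RadiodensitySample, bin_width: float = 5.0
) -> SampleSummary:
    """Mean, sample sd and a histogram of a region's radiodensity readings.

    Histogram bins are ``bin_width`` HU wide (default 5) and cover the
    observed range.
    """
    vals = sample.values
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return SampleSummary(mean=sample.mean, sd=sample.sd, bin_edges=edges, counts=counts)


def fit_two_point(hu_zero: float, hu_hundred: float) -> CalibrationModel:
    """Build the two-point calibration from the 0% and 100% ethanol standards.

    The returned model reproduces the standards exactly:
    ``estimate_concentration(hu_zero) == 0`` and
    ``estimate_concentration(hu_hundred) == 1``.
    """
    return CalibrationModel(hu_zero=float(hu_zero), hu_hundred=float(hu_hundred))


def estimate_concentration(hu, model: CalibrationModel):
    """Estimated ethanol fraction for radiodensity ``hu`` (scalar or array).

    The estimate is *not* clipped: values below 0 or above 1 are returned
    as-is; exclusion policy (e.g. the >120% air-bubble cut applied in vivo)
    belongs to the volumetrics stage.
    """
    hu = np.asarray(hu, dtype=float)
    out = (hu - model.hu_zero) / (model.hu_hundred - model.hu_zero)
    return float(out) if out.ndim == 0 else out


def fit_linear(samples: Sequence[RadiodensitySample]) -> LinearFitResult:
    """OLS diagnostic fit of per-sample mean HU against known concentration.

    Requires at least two distinct known concentrations.  This is the
    goodness-of-linearity check; the two-point model remains the working
    calibration.
    """
    known = [s for s in samples if s.true_concentration is not None]
    concs = np.array([s.true_concentration for s in known], dtype=float)
    if np.unique(concs).size < 2:
        raise CalibrationError("need >= 2 distinct known concentrations for a fit")
    means = np.array([s.mean for s in known])
    res = stats.linregress(concs, means)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def nonlinearity_error(
    model: CalibrationModel, intermediates: Sequence[RadiodensitySample]
) -> tuple[float, float]:
    """Systematic calibration error at intermediate concentrations.

    For each sample with known true concentration strictly inside (0, 1), the
    error is ``|c_est(mean HU) - c_true| * 100`` in concentration percentage
    points.  Returns the mean and sample sd over all intermediates.
    """
    errors = []
    for s in intermediates:
        if s.true_concentration is None:
            raise CalibrationError(f"intermediate {s.label!r} has unknown truth")
        if not (0.0 < s.true_concentration < 1.0):
            raise CalibrationError(
                f"intermediate {s.label!r} concentration {s.true_concentration} "
                "not strictly inside (0, 1)"
            )
        est = estimate_concentration(s.mean, model)
        errors.append(abs(est - s.true_concentration) * 100.0)
    arr = np.array(errors)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def measurement_variance(
    samples: Sequence[RadiodensitySample], model: CalibrationModel
) -> tuple[float, float, float]:
    """Random measurement error from homogeneous-sample radiodensity spread.

    Returns ``(variance_hu_mean, variance_hu_sd, variance_pct_of_range)``:
    the mean and sd of per-sample standard deviations, and the mean expressed
    as a percentage of the calibration range.
    """
    if not samples:
        raise CalibrationError("need >= 1 sample")
    sds = np.array([s.sd for s in samples])
    mean_sd = float(sds.mean())
    sd_sd = float(np.std(sds, ddof=1)) if sds.size > 1 else 0.0
    return mean_sd, sd_sd, 100.0 * mean_sd / model.hu_range


def error_report(
    model: CalibrationModel,
    intermediates: Sequence[RadiodensitySample],
    vials: Sequence[RadiodensitySample],
) -> CalibrationErrorReport:
    """Combine non-linearity and variance diagnostics into one report."""
    nl_mean, nl_sd = nonlinearity_error(model, intermediates)
    v_mean, v_sd, v_pct = measurement_variance(vials, model)
    return CalibrationErrorReport(
        nonlinearity_error_mean=nl_mean,
        nonlinearity_error_sd=nl_sd,
        variance_hu_mean=v_mean,
        variance_hu_sd=v_sd,
        variance_pct_of_range=v_pct,
    )
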