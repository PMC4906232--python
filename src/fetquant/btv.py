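"""Threshold-based biological tumor volume (BTV) segmentation and the
SUVmax/BG-calibrated individual-threshold model.

The clinical standard delineates the BTV as the set of voxels whose
SUV/BG exceeds a fixed threshold (1.4/1.6/1.8/2.0 are the commonly used
values). In the glioblastoma mouse model no single fixed threshold tracks
the histological reference volume; instead, the 'optimal' individual
threshold — the one whose hot-connected volume best matches the reference
— is almost perfectly linear in the animal's SUVmax/BG:

    threshold = 0.3215 * SUVmax/BG + 0.5654

(the default calibration shipped with this module). Fitting that line on
a calibration cohort and predicting thresholds from SUVmax/BG alone gives
individual BTVs without histology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats

from .geometry import ActivityImage, VOIMask

__all__ = [
    "BTVResult",
    "CalibrationModel",
    "VolumeComparison",
    "BTVError",
    "ThresholdPlausibilityWarning",
    "DEFAULT_CALIBRATION",
    "default_calibration",
    "segment_btv",
    "volume_threshold_curve",
    "find_optimal_threshold",
    "fit_calibration",
    "predict_threshold",
    "rms_percent_error",
    "compare_volumes",
    "STANDARD_THRESHOLDS",
]

#: Predefined SUV/BG thresholds from clinical routine.
STANDARD_THRESHOLDS = (1.4, 1.6, 1.8, 2.0)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

Mode = Literal["hot-connected", "all-voxels"]


class BTVError(ValueError):
    """Invalid input to a BTV operation."""


class ThresholdPlausibilityWarning(UserWarning):
    """Predicted threshold at or below the background level (SUV/BG <= 1)."""


@dataclass
class BTVResult:
    """A segmented biological tumor volume."""

    threshold: float
    mask: VOIMask
    volume_mm3: float
    mode: Mode
    search_region_label: str = ""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from SUVmax/BG (x) to the individual BTV threshold (y)."""

    slope: float
    intercept: float
    n: int | None = None
    pearson_rho: float | None = None
    p_value: float | None = None


def default_calibration() -> CalibrationModel:
    """The published calibration y = 0.3215 x + 0.5654 (8-animal fit)."""
    return CalibrationModel(slope=0.3215, intercept=0.5654, n=8)


DEFAULT_CALIBRATION = default_calibration()


@dataclass(frozen=True)
class VolumeComparison:
    """Per-case estimated vs reference volumes and the group RMSE percent."""

    estimated_mm3: tuple[float, ...]
    reference_mm3: tuple[float, ...]
    percent_errors: tuple[float, ...]
    rmse_percent: float


def _hot_connected(
    values: np.ndarray, region: np.ndarray, suprathreshold: np.ndarray
) -> np.ndarray:
    """26-connected component of the suprathreshold set containing the
    hottest voxel of the search region (empty if that voxel is below
    threshold)."""
    flat_hot = np.argmax(np.where(region, values, -np.inf))
    hot_idx = np.unravel_index(flat_hot, values.shape)
    if not suprathreshold[hot_idx]:
        return np.zeros_like(suprathreshold)
    labels, _ = ndimage.label(suprathreshold, structure=_STRUCT_26)
    return labels == labels[hot_idx]


def segment_btv(
    image: ActivityImage,
    bg_mean: float,
    threshold: float,
    search_region: VOIMask,
    mode: Mode = "hot-connected",
) -> BTVResult:
    """Voxels of the search region with value/bg_mean >= threshold.

    ``hot-connected`` keeps only the 26-connected suprathreshold component
    containing the hottest voxel of the search region ('hot 3D VOI
    assignment'); ``all-voxels`` keeps the full suprathreshold set.
    """
    if bg_mean <= 0:
        raise BTVError("bg_mean must be > 0")
    if threshold <= 0:
        raise BTVError("threshold must be > 0")
    search_region.check_same_geometry(image.geometry)
    if search_region.count == 0:
        raise BTVError("search region is empty")
    if mode not in ("hot-connected", "all-voxels"):
        raise BTVError(f"unknown mode {mode!r}")
    supra = search_region.members & (image.values >= threshold * bg_mean)
    members = supra if mode == "all-voxels" else _hot_connected(image.values, search_region.members, supra)
    mask = VOIMask(image.geometry, members, label=f"btv_{threshold:g}")
    return BTVResult(
        threshold=float(threshold),
        mask=mask,
        volume_mm3=mask.volume_mm3,
        mode=mode,
        search_region_label=search_region.label,
    )


def volume_threshold_curve(
    image: ActivityImage,
    bg_mean: float,
    search_region: VOIMask,
    thresholds: Sequence[float],
    mode: Mode = "hot-connected",
) -> list[tuple[float, float]]:
    """BTV volume at each threshold (thresholds ascending; volumes are
    non-increasing by nestedness of suprathreshold sets)."""
    thresholds = [float(t) for t in thresholds]
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise BTVError("thresholds must be sorted ascending")
    return [
        (t, segment_btv(image, bg_mean, t, search_region, mode).volume_mm3) for t in thresholds
    ]


def find_optimal_threshold(
    image: ActivityImage,
    bg_mean: float,
    reference_volume_mm3: float,
    search_region: VOIMask,
    mode: Mode = "hot-connected",
) -> tuple[float, BTVResult]:
    """Exact search for the threshold whose BTV best matches a reference.

    Candidate thresholds are every distinct value/bg_mean over the search
    region plus a sentinel above the maximum (empty volume); the candidate
    minimizing |volume - reference| wins, ties resolved toward the smaller
    threshold (the larger volume, avoiding clipping of the tumor rim).
    """
    if reference_volume_mm3 <= 0:
        raise BTVError("reference volume must be > 0")
    if bg_mean <= 0:
        raise BTVError("bg_mean must be > 0")
    search_region.check_same_geometry(image.geometry)
    if search_region.count == 0:
        raise BTVError("search region is empty")
    vv = image.geometry.voxel_volume_mm3
    if reference_volume_mm3 < vv:
        warnings.warn(
            f"reference volume {reference_volume_mm3:.4f} mm^3 is smaller than one voxel "
            f"({vv:.4f} mm^3); the search degenerates to a single-voxel or empty BTV",
            stacklevel=2,
        )

    # Work on the bounding box of the search region: every operation is local.
    idx = np.nonzero(search_region.members)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = image.values[box]
    region = search_region.members[box]

    candidates = np.unique(vals[region]) / bg_mean
    candidates = candidates[candidates > 0]
    sentinel = (candidates[-1] if candidates.size else 1.0) * (1 + 1e-9) + 1e-12
    candidates = np.append(candidates, sentinel)

    best_theta, best_err = None, np.inf
    for theta in candidates:  # ascending: first minimum keeps the smaller theta
        supra = region & (vals >= theta * bg_mean)
        if mode == "all-voxels":
            n_members = int(supra.sum())
        else:
            n_members = int(_hot_connected(vals, region, supra).sum())
        err = abs(n_members * vv - reference_volume_mm3)
        if err < best_err - 1e-12:
            best_theta, best_err = float(theta), err
    result = segment_btv(image, bg_mean, best_theta, search_region, mode)
    return best_theta, result


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of the optimal threshold (y) on SUVmax/BG (x),
    with Pearson rho and its two-sided t-test p-value (df = n - 2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise BTVError("need at least 3 (suvmax_bg, optimal_threshold) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise BTVError("SUVmax/BG values are all equal; calibration is degenerate")
    if np.ptp(y) == 0:
        # Flat response: slope 0, rho 0 by convention.
        return CalibrationModel(0.0, float(y[0]), n=len(y), pearson_rho=0.0, p_value=1.0)
    fit = stats.linregress(x, y)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
        pearson_rho=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )


def predict_threshold(suvmax_bg: float, model: CalibrationModel | None = None) -> float:
    """Individual BTV threshold predicted from SUVmax/BG: slope * x + intercept.

    Emits :class:`ThresholdPlausibilityWarning` when the prediction falls to
    or below 1 (the background level), which happens for SUVmax/BG below
    about 1.35 with the default calibration.
    """
    if suvmax_bg < 0:
        raise BTVError("suvmax_bg must be >= 0")
    model = model or DEFAULT_CALIBRATION
    y = model.slope * suvmax_bg + model.intercept
    if y <= 1.0:
        warnings.warn(
            f"predicted threshold {y:.4f} <= 1 (background level) for SUVmax/BG {suvmax_bg:.3f}",
            ThresholdPlausibilityWarning,
            stacklevel=2,
        )
    return float(y)


def compare_volumes(
    estimated_mm3: Sequence[float], reference_mm3: Sequence[float]
) -> VolumeComparison:
    """Per-case percent errors 100 (est - ref)/ref and the group RMSE."""
    est = np.asarray(estimated_mm3, dtype=float)
    ref = np.asarray(reference_mm3, dtype=float)
    if est.size == 0 or est.shape != ref.shape:
        raise BTVError("estimated and reference volumes must be equal-length and non-empty")
    if np.any(ref <= 0):
        raise BTVError("reference volumes must all be > 0")
    errors = 100.0 * (est - ref) / ref
    return VolumeComparison(
        estimated_mm3=tuple(est),
        reference_mm3=tuple(ref),
        percent_errors=tuple(errors),
        rmse_percent=float(np.sqrt(np.mean(errors**2))),
    )


def rms_percent_error(
    estimated_mm3: Sequence[float], reference_mm3: Sequence[float]
) -> float:
    """Root-mean-square of the per-case percent volume errors."""
    return compare_volumes(estimated_mm3, reference_mm3).rmse_percent
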