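"""Background-normalized SUV statistics, bone spill-in screening, and the
error measure against the ex vivo autoradiographic reference.

All quantities of interest are ratios to the mean activity of the large
contralateral background VOI (SUVmean/BG, SUVmax/BG), so the absolute SUV
normalization by injected dose and body weight cancels; an absolute-SUV
utility is provided but never required downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import ActivityImage, VOIMask

__all__ = [
    "UptakeStats",
    "SpillInReport",
    "AutoradReference",
    "QuantError",
    "region_uptake_stats",
    "screen_spill_in",
    "error_percent",
    "autorad_reference",
    "absolute_suv",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class QuantError(ValueError):
    """Invalid input to a quantification operation."""


@dataclass(frozen=True)
class UptakeStats:
    """Per-animal uptake statistics in a target VOI.

    ``suv_max_bg`` is the x of the individual-threshold calibration.
    """

    suv_mean: float
    suv_max: float
    suv_mean_bg: float
    suv_max_bg: float
    bg_mean: float
    excluded_voxels: int


@dataclass
class SpillInReport:
    """Rim voxels suspected to carry bone spill-in rather than tumor signal."""

    flagged_voxels: np.ndarray  # (n, 3) integer indices
    flagged_values_bg: np.ndarray  # SUV/BG of flagged voxels
    exclusion: VOIMask  # suggested exclusion (subset of the target rim)
    tumor_attributable_max_bg: float  # max SUV/BG after exclusion


@dataclass(frozen=True)
class AutoradReference:
    """Autoradiographic SUVmean/BG reference from per-slice ROI means."""

    slice_ratios: tuple[float, ...]
    n_slices: int
    suv_mean_bg: float


def region_uptake_stats(
    image: ActivityImage,
    target: VOIMask,
    background: VOIMask,
    exclusion: VOIMask | None = None,
) -> UptakeStats:
    """SUVmean/SUVmax over the target VOI, each divided by the background mean.

    ``exclusion`` removes voxels (e.g. confirmed bone spill-in) from the
    target before the statistics are formed.
    """
    target.check_same_geometry(image.geometry)
    background.check_same_geometry(image.geometry)
    if background.count == 0:
        raise QuantError("background VOI is empty")
    effective = target.members
    excluded = 0
    if exclusion is not None:
        exclusion.check_same_geometry(image.geometry)
        excluded = int((target.members & exclusion.members).sum())
        effective = target.members & ~exclusion.members
    if not effective.any():
        raise QuantError("target VOI is empty after exclusion")
    bg_mean = float(image.values[background.members].mean())
    if bg_mean <= 0:
        raise QuantError(f"background mean must be > 0, got {bg_mean}")
    vals = image.values[effective]
    suv_mean = float(vals.mean())
    suv_max = float(vals.max())
    return UptakeStats(
        suv_mean=suv_mean,
        suv_max=suv_max,
        suv_mean_bg=suv_mean / bg_mean,
        suv_max_bg=suv_max / bg_mean,
        bg_mean=bg_mean,
        excluded_voxels=excluded,
    )


def screen_spill_in(
    image: ActivityImage,
    target: VOIMask,
    background: VOIMask,
    rim_width: int = 1,
    factor: float = 1.0,
) -> SpillInReport:
    """Screen the target VOI rim for bone spill-in.

    Spill-in from cranium-bound [18F] fluoride appears at the very edge of
    the universal target VOI; this automates the slice-by-slice manual
    control by flagging voxels in the outer ``rim_width``-voxel shell whose
    SUV/BG exceeds ``factor`` times the maximum of the VOI interior. The
    suggested exclusion mask is the union of the flagged voxels'
    26-connected suprathreshold components, intersected with the rim;
    whether to apply it remains the analyst's decision.
    """
    if rim_width < 1:
        raise QuantError("rim_width must be >= 1")
    if factor <= 0:
        raise QuantError("factor must be > 0")
    target.check_same_geometry(image.geometry)
    stats = region_uptake_stats(image, target, background)
    ratio = image.values / stats.bg_mean

    interior = ndimage.binary_erosion(target.members, structure=_STRUCT_26, iterations=rim_width)
    if not interior.any():
        raise QuantError("target interior is empty after rim removal")
    rim = target.members & ~interior
    interior_max = float(ratio[interior].max())
    threshold = factor * interior_max

    suprathreshold = target.members & (ratio > threshold)
    flagged = rim & suprathreshold
    exclusion = np.zeros_like(flagged)
    if flagged.any():
        labels, _ = ndimage.label(suprathreshold, structure=_STRUCT_26)
        hit = np.unique(labels[flagged])
        exclusion = np.isin(labels, hit[hit > 0]) & rim
    remaining = target.members & ~exclusion
    return SpillInReport(
        flagged_voxels=np.argwhere(flagged),
        flagged_values_bg=ratio[flagged],
        exclusion=VOIMask(image.geometry, exclusion, label="spill_in_exclusion"),
        tumor_attributable_max_bg=float(ratio[remaining].max()),
    )


def error_percent(pet_value: float, reference_value: float) -> float:
    """Percent deviation of a PET estimate from the high-resolution reference:
    100 * (pet - reference) / reference."""
    if reference_value <= 0:
        raise QuantError("reference value must be > 0")
    return 100.0 * (pet_value - reference_value) / reference_value


def autorad_reference(
    slice_tumor_means: Sequence[float], slice_bg_means: Sequence[float]
) -> AutoradReference:
    """Autoradiographic SUVmean/BG: per-slice tumor/background ratio, then
    the arithmetic mean across slices.

    Slice-wise ratios are robust to per-plate exposure scaling, which is
    why the ratio is formed before averaging.
    """
    tumor = np.asarray(slice_tumor_means, dtype=float)
    bg = np.asarray(slice_bg_means, dtype=float)
    if tumor.size == 0 or tumor.shape != bg.shape:
        raise QuantError("tumor and background slice means must be equal-length and non-empty")
    if np.any(tumor <= 0) or np.any(bg <= 0):
        raise QuantError("slice ROI means must all be > 0")
    ratios = tumor / bg
    return AutoradReference(
        slice_ratios=tuple(float(r) for r in ratios),
        n_slices=int(tumor.size),
        suv_mean_bg=float(ratios.mean()),
    )


def absolute_suv(concentration: float, injected_dose: float, body_weight: float) -> float:
    """Absolute SUV = concentration * body weight / injected dose.

    Units must be consistent (e.g. kBq/mL, g, kBq). Provided for
    completeness; every supported endpoint is a background ratio in which
    this normalization cancels.
    """
    if injected_dose <= 0 or body_weight <= 0:
        raise QuantError("injected dose and body weight must be > 0")
    return concentration * body_weight / injected_dose
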