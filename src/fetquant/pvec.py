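"""Geometric-transfer-matrix (GTM) partial volume effect correction.

The limited scanner resolution mixes signal between neighboring tissue
domains. For a set of disjoint regions, blurring each region's indicator
function with the scanner PSF and averaging the result over every region
yields the transfer coefficient w_ij: the fraction of region j's true
signal observed in region i. Measured regional means m then satisfy
W t = m for the true means t, which are recovered by a linear solve
(never an explicit inverse — the 8x8 matrix can be near-singular for
thin regions, so the condition number is always reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ActivityImage, RegionSet
from .phantom import DEFAULT_FWHM, apply_psf

__all__ = [
    "GTMMatrix",
    "CorrectedMeans",
    "GTMConditioningError",
    "compute_gtm",
    "measure_region_means",
    "correct_regional_means",
    "render_corrected_image",
    "coverage_fraction",
]


class GTMConditioningError(ValueError):
    """The transfer matrix is too ill-conditioned to invert reliably."""


@dataclass(frozen=True)
class GTMMatrix:
    """Region-by-region spill-over coefficients.

    ``w[i, j]`` is the fraction of region j's true signal observed in
    region i. Rows are substochastic; they sum to 1 (within 1e-6) exactly
    when the regions tile the image support.
    """

    labels: tuple[str, ...]
    w: np.ndarray
    condition_number: float
    fwhm: tuple[float, float, float] = DEFAULT_FWHM

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(self.labels), len(self.labels)):
            raise ValueError("GTM must be square with one row per region")
        if np.any(w < -1e-9) or np.any(w > 1 + 1e-6):
            raise ValueError("GTM coefficients must lie in [0, 1]")
        if np.any(w.sum(axis=1) > 1 + 1e-6):
            raise ValueError("GTM row sums must not exceed 1")


@dataclass(frozen=True)
class CorrectedMeans:
    """PVE-corrected per-region activity estimates."""

    labels: tuple[str, ...]
    corrected: np.ndarray
    measured: np.ndarray
    fwhm: tuple[float, float, float]


def compute_gtm(
    regions: RegionSet,
    fwhm: Sequence[float] = DEFAULT_FWHM,
    condition_limit: float = 1e6,
) -> GTMMatrix:
    """Transfer coefficients by blurring each region indicator with the PSF.

    Raises
    ------
    GTMConditioningError
        If the condition number exceeds ``condition_limit`` (default 1e6).
    """
    masks = regions.masks
    n = len(masks)
    w = np.empty((n, n), dtype=float)
    for j, mask_j in enumerate(masks):
        indicator = ActivityImage(regions.geometry, mask_j.members.astype(np.float64))
        blurred = apply_psf(indicator, fwhm).values
        for i, mask_i in enumerate(masks):
            w[i, j] = float(blurred[mask_i.members].mean())
    cond = float(np.linalg.cond(w))
    if cond > condition_limit:
        raise GTMConditioningError(
            f"GTM condition number {cond:.3g} exceeds limit {condition_limit:.3g}"
        )
    return GTMMatrix(
        labels=tuple(regions.labels),
        w=w,
        condition_number=cond,
        fwhm=tuple(float(f) for f in fwhm),
    )


def measure_region_means(image: ActivityImage, regions: RegionSet) -> np.ndarray:
    """Mean image value over each region, in region order."""
    for mask in regions.masks:
        mask.check_same_geometry(image.geometry)
    return np.array([float(image.values[m.members].mean()) for m in regions.masks])


def correct_regional_means(measured: Sequence[float], gtm: GTMMatrix) -> CorrectedMeans:
    """Recover true regional means by solving W t = m.

    Negative corrected means are physically implausible (they indicate
    noise or unmodeled activity) and trigger a warning, not an error.
    """
    m = np.asarray(measured, dtype=float)
    if m.shape != (len(gtm.labels),):
        raise ValueError(
            f"measured means length {m.shape} does not match the {len(gtm.labels)}-region GTM"
        )
    t = np.linalg.solve(gtm.w, m)
    if np.any(t < -1e-9):  # tolerate round-off on zero-activity regions
        warnings.warn(
            f"PVEC produced negative corrected means for regions "
            f"{[gtm.labels[i] for i in np.nonzero(t < -1e-9)[0]]}",
            stacklevel=2,
        )
    return CorrectedMeans(labels=gtm.labels, corrected=t, measured=m, fwhm=gtm.fwhm)


def render_corrected_image(corrected: CorrectedMeans, regions: RegionSet) -> ActivityImage:
    """Piecewise-constant PVE-corrected image: voxel in region j gets t_j.

    Voxels outside every region are set to 0; the corrected image contains
    only the regions with VOI-mask definitions, so a coverage warning is
    emitted when part of the grid is unmodeled.
    """
    if len(corrected.labels) != len(regions):
        raise ValueError("corrected means do not match the region set")
    values = np.zeros(regions.geometry.shape, dtype=np.float64)
    for t_j, mask in zip(corrected.corrected, regions.masks):
        values[mask.members] = t_j
    if not regions.union().all():
        warnings.warn(
            "PVE-corrected image covers only the masked regions; "
            "voxels outside all regions were set to 0",
            stacklevel=2,
        )
    return ActivityImage(regions.geometry, values)


def coverage_fraction(image: ActivityImage, regions: RegionSet) -> float:
    """Fraction of total image activity that falls outside every region.

    Unmodeled activity violates the GTM model assumptions and biases the
    correction, so this diagnostic is part of every PVEC report.
    """
    total = float(image.values.sum())
    if total == 0:
        return 0.0
    outside = float(image.values[~regions.union()].sum())
    return outside / total
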