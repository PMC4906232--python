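"""Cavalieri reference volumetry from sectional ROI areas.

The histological reference volume is estimated stereologically: the brain
is cut into 16 um horizontal sections, every 24th section is mounted
(section spacing d = 0.384 mm), tumor ROIs are drawn on each mounted
section, and the volume is the sum of ROI areas times the spacing:

    V = (sum of areas) * thickness * interval

Mounting every k-th section is treated as systematic uniform random
sampling, so closed-loop tests average over the section phase offset.
``sample_section_areas`` cuts synthetic sections from a phantom truth
mask so the whole reference-measurement loop can be exercised without
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VOIMask

__all__ = ["SectionSeries", "HistologyError", "cavalieri_volume", "sample_section_areas"]


class HistologyError(ValueError):
    """Invalid section series or sampling parameters."""


@dataclass(frozen=True)
class SectionSeries:
    """ROI areas of systematically sampled sections, in anatomical order.

    ``shrinkage_factor`` is an optional multiplicative area correction for
    tissue shrinkage during preparation; the default 1.0 applies none.
    """

    areas_mm2: tuple[float, ...]
    section_thickness_mm: float = 0.016
    sampling_interval: int = 24
    shrinkage_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas_mm2", tuple(float(a) for a in self.areas_mm2))
        if len(self.areas_mm2) == 0:
            raise HistologyError("a section series needs at least one section")
        if any(a < 0 for a in self.areas_mm2):
            raise HistologyError("section areas must be >= 0")
        if self.section_thickness_mm <= 0:
            raise HistologyError("section thickness must be > 0")
        if self.sampling_interval < 1:
            raise HistologyError("sampling interval must be >= 1")
        if self.shrinkage_factor <= 0:
            raise HistologyError("shrinkage factor must be > 0")

    @property
    def spacing_mm(self) -> float:
        """Distance between consecutive sampled sections."""
        return self.section_thickness_mm * self.sampling_interval


def cavalieri_volume(series: SectionSeries) -> float:
    """Cavalieri estimator: V = sum(areas) * thickness * interval.

    Linear in the areas and exact for prisms aligned with the cutting
    axis; unbiased for arbitrary shapes under uniform random phase.
    """
    return float(sum(series.areas_mm2)) * series.spacing_mm * series.shrinkage_factor


def sample_section_areas(
    truth_mask: VOIMask,
    plane_axis: int = 2,
    spacing_mm: float = 0.384,
    phase_mm: float = 0.0,
) -> SectionSeries:
    """Cut synthetic sections from a voxel mask.

    Planes are placed at ``phase + k * spacing`` (world coordinates along
    ``plane_axis``) across the grid extent; each plane's area is the
    member count of the voxel slab it falls in times the in-plane voxel
    area. Returns a series whose thickness * interval equals the plane
    spacing so that :func:`cavalieri_volume` applies unchanged.
    """
    if plane_axis not in (0, 1, 2):
        raise HistologyError(f"plane_axis must be 0, 1 or 2, got {plane_axis}")
    if spacing_mm <= 0:
        raise HistologyError("plane spacing must be > 0")
    geom = truth_mask.geometry
    d = geom.spacing[plane_axis]
    n_axis = geom.shape[plane_axis]
    in_plane_area = geom.voxel_volume_mm3 / d

    counts = truth_mask.members.sum(axis=tuple(a for a in range(3) if a != plane_axis))

    axis_lo = geom.origin[plane_axis] - d / 2.0  # lower face of the first slab
    axis_hi = axis_lo + n_axis * d
    k_start = int(np.ceil((axis_lo - phase_mm) / spacing_mm))
    areas = []
    k = k_start
    while True:
        z = phase_mm + k * spacing_mm
        if z >= axis_hi:
            break
        slab = int(np.floor((z - axis_lo) / d))
        areas.append(float(counts[slab]) * in_plane_area)
        k += 1
    if not areas:
        areas = [0.0]
    return SectionSeries(areas_mm2=tuple(areas), section_thickness_mm=spacing_mm, sampling_interval=1)
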