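"""Voxel-grid geometry, image/mask containers, NIfTI-1 I/O, and universal VOIs.

Conventions
-----------
* Voxel indices are 0-based; the world position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (voxel-center convention). All world
  coordinates and spacings are in millimetres, volumes in mm^3.
* The third array axis is the axial (cranio-caudal) direction and carries
  the coarser spacing of the reconstruction grid (0.80 mm by default).
* Images are stored as NIfTI-1 with a diagonal affine; masks are unsigned
  8-bit volumes with 1 = member.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "FormatError",
    "ImageGeometry",
    "ActivityImage",
    "VOIMask",
    "RegionSet",
    "voxel_volume",
    "load_activity_image",
    "save_activity_image",
    "load_voi_mask",
    "save_voi_mask",
    "box_voi",
    "make_universal_vois",
    "DEFAULT_SPACING",
]

#: In-plane x, in-plane y, axial z voxel edge lengths of the reconstruction
#: grid (mm).
DEFAULT_SPACING = (0.39, 0.39, 0.80)


class GeometryError(ValueError):
    """Invalid grid geometry or mask/geometry mismatch."""


class FormatError(ValueError):
    """File contents violate the expected on-disk format."""


@dataclass(frozen=True)
class ImageGeometry:
    """A regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``.
    spacing
        Voxel edge lengths in mm.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GeometryError("shape, spacing and origin must be length-3")
        if any(n < 1 for n in self.shape):
            raise GeometryError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine (mm)."""
        return nib.affines.from_matvec(np.diag(self.spacing), self.origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse meshgrid of world coordinates (broadcastable to `shape`)."""
        return tuple(
            np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij", sparse=True)
        )

    def world_to_index(self, point: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a world point."""
        return (np.asarray(point, dtype=float) - self.origin) / np.asarray(self.spacing)

    def index_to_world(self, index: Sequence[float]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def contains_point(self, point: Sequence[float]) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1))


def voxel_volume(geometry: ImageGeometry) -> float:
    """Volume of a single voxel in mm^3 (product of the three spacings)."""
    return geometry.voxel_volume_mm3


@dataclass
class ActivityImage:
    """A 3-D scalar activity-concentration field on a voxel grid.

    Values are in arbitrary concentration units (e.g. kBq/mL); every
    quantity of interest downstream is a background ratio in which the
    absolute scale cancels.
    """

    geometry: ImageGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError("activity values must be a 3-D array")
        if tuple(self.values.shape) != self.geometry.shape:
            raise GeometryError(
                f"value grid {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("activity values must be finite")


@dataclass
class VOIMask:
    """Boolean voxel membership defining a volume of interest."""

    geometry: ImageGeometry
    members: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.ndim != 3 or tuple(self.members.shape) != self.geometry.shape:
            raise GeometryError("mask grid does not match its geometry")

    @property
    def count(self) -> int:
        return int(self.members.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.geometry.voxel_volume_mm3

    def check_same_geometry(self, other_geometry: ImageGeometry) -> None:
        if self.geometry != other_geometry:
            raise GeometryError(f"mask '{self.label}' geometry differs from image geometry")


@dataclass
class RegionSet:
    """An ordered collection of pairwise-disjoint labeled VOIs.

    The partial-volume correction uses an 8-region set (individual tumor
    VOI, rest of cerebrum, and six extracerebral regions), but any >= 2
    disjoint regions are accepted.
    """

    geometry: ImageGeometry
    regions: list[tuple[str, VOIMask]]

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise GeometryError("a region set needs at least 2 regions")
        occupancy = np.zeros(self.geometry.shape, dtype=np.uint8)
        for label, mask in self.regions:
            mask.check_same_geometry(self.geometry)
            occupancy += mask.members
        if occupancy.max() > 1:
            raise GeometryError("region masks must be pairwise disjoint")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.regions]

    @property
    def masks(self) -> list[VOIMask]:
        return [mask for _, mask in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def union(self) -> np.ndarray:
        out = np.zeros(self.geometry.shape, dtype=bool)
        for _, mask in self.regions:
            out |= mask.members
        return out

    def to_labeled_array(self) -> np.ndarray:
        """Labeled volume with region ``i`` encoded as ``i + 1`` (0 = outside)."""
        out = np.zeros(self.geometry.shape, dtype=np.uint8)
        for i, (_, mask) in enumerate(self.regions):
            out[mask.members] = i + 1
        return out

    @classmethod
    def from_labeled_array(
        cls, geometry: ImageGeometry, labeled: np.ndarray, labels: Sequence[str]
    ) -> "RegionSet":
        labeled = np.asarray(labeled)
        regions = [
            (str(label), VOIMask(geometry, labeled == i + 1, label=str(label)))
            for i, label in enumerate(labels)
        ]
        return cls(geometry, regions)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------


def _geometry_from_nifti(img: nib.Nifti1Image) -> ImageGeometry:
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3-D volume, got shape {img.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"missing or non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageGeometry(shape=tuple(img.shape), spacing=tuple(float(z) for z in zooms), origin=origin)


def save_activity_image(image: ActivityImage, path: str | Path) -> None:
    """Write an activity image as NIfTI-1 (float64, diagonal affine)."""
    nifti = nib.Nifti1Image(image.values.astype(np.float64), image.geometry.affine)
    nifti.header.set_data_dtype(np.float64)
    nifti.header.set_zooms(image.geometry.spacing)
    nib.save(nifti, str(path))


def load_activity_image(path: str | Path) -> ActivityImage:
    """Load a 3-D NIfTI-1 scalar volume; round-trips :func:`save_activity_image` bit-exactly."""
    nifti = nib.load(str(path))
    geometry = _geometry_from_nifti(nifti)
    values = np.asarray(nifti.get_fdata(dtype=np.float64))
    return ActivityImage(geometry, values)


def save_voi_mask(mask: VOIMask, path: str | Path) -> None:
    """Write a mask as NIfTI-1 unsigned 8-bit, 1 = member."""
    nifti = nib.Nifti1Image(mask.members.astype(np.uint8), mask.geometry.affine)
    nifti.header.set_data_dtype(np.uint8)
    nifti.header.set_zooms(mask.geometry.spacing)
    nib.save(nifti, str(path))


def load_voi_mask(path: str | Path, label: str = "") -> VOIMask:
    nifti = nib.load(str(path))
    geometry = _geometry_from_nifti(nifti)
    values = np.asarray(nifti.get_fdata(dtype=np.float64))
    unique = np.unique(values)
    if not np.all(np.isin(unique, (0.0, 1.0))):
        raise FormatError(f"mask file contains values other than 0/1: {unique[:10]}")
    return VOIMask(geometry, values > 0.5, label=label or Path(path).stem)


def save_geometry_sidecar(geometry: ImageGeometry, path: str | Path) -> None:
    """Optional JSON sidecar with the grid definition."""
    with open(path, "w") as fh:
        json.dump(
            {"shape": geometry.shape, "spacing_mm": geometry.spacing, "origin_mm": geometry.origin},
            fh,
            indent=2,
        )


# ---------------------------------------------------------------------------
# Universal VOIs
# ---------------------------------------------------------------------------


def box_voi(
    geometry: ImageGeometry,
    center: Sequence[float],
    volume_mm3: float,
    footprint_mm: tuple[float, float] | None = None,
    label: str = "",
) -> VOIMask:
    """Axis-aligned box VOI with the nearest achievable voxel count.

    The box is centered on the given world coordinate. Full axial slabs are
    stacked over an ``nx x ny`` in-plane footprint; the final slab is filled
    partially (voxels nearest the box center first) so that the member count
    equals ``round(volume_mm3 / voxel_volume)`` exactly. With the default
    near-cubic footprint and the 0.39 x 0.39 x 0.80 mm grid, an 88 mm^3
    request yields 723 voxels (87.97 mm^3).

    Parameters
    ----------
    footprint_mm
        Optional in-plane (x, y) extent of the box in mm; defaults to the
        cube root of the requested volume (near-cubic box).
    """
    if volume_mm3 <= 0:
        raise GeometryError("VOI volume must be > 0")
    if not geometry.contains_point(center):
        raise GeometryError(f"VOI center {tuple(center)} lies outside the grid")
    vv = geometry.voxel_volume_mm3
    n_target = max(1, int(round(volume_mm3 / vv)))
    edge = volume_mm3 ** (1.0 / 3.0)
    fx, fy = footprint_mm if footprint_mm is not None else (edge, edge)
    cx = max(1, int(round(fx / geometry.spacing[0])))
    cy = max(1, int(round(fy / geometry.spacing[1])))
    per_slab = cx * cy
    nz_full, remainder = divmod(n_target, per_slab)

    ci = np.round(geometry.world_to_index(center)).astype(int)
    x_lo = ci[0] - (cx - 1) // 2
    y_lo = ci[1] - (cy - 1) // 2
    z_lo = ci[2] - (nz_full - 1) // 2 if nz_full else ci[2]
    z_hi = z_lo + nz_full  # exclusive; partial slab sits at z_hi

    nz_extent = nz_full + (1 if remainder else 0)
    if (
        x_lo < 0
        or y_lo < 0
        or z_lo < 0
        or x_lo + cx > geometry.shape[0]
        or y_lo + cy > geometry.shape[1]
        or z_lo + nz_extent > geometry.shape[2]
    ):
        raise GeometryError(
            f"VOI '{label}' of {volume_mm3} mm^3 at {tuple(center)} is clipped by the grid boundary"
        )

    members = np.zeros(geometry.shape, dtype=bool)
    members[x_lo : x_lo + cx, y_lo : y_lo + cy, z_lo:z_hi] = True
    if remainder:
        # Fill the final slab from the center outwards (deterministic order).
        xs = np.arange(x_lo, x_lo + cx)
        ys = np.arange(y_lo, y_lo + cy)
        xv, yv = np.meshgrid(xs, ys, indexing="ij")
        d2 = ((xv - ci[0]) * geometry.spacing[0]) ** 2 + ((yv - ci[1]) * geometry.spacing[1]) ** 2
        order = np.lexsort((yv.ravel(), xv.ravel(), d2.ravel()))
        pick = order[:remainder]
        members[xv.ravel()[pick], yv.ravel()[pick], z_hi] = True
    return VOIMask(geometry, members, label=label)


def make_universal_vois(
    geometry: ImageGeometry,
    tumor_center: Sequence[float],
    bg_center: Sequence[float],
    tumor_volume_mm3: float = 88.0,
    bg_volume_mm3: float = 123.0,
    tumor_footprint_mm: tuple[float, float] | None = None,
    bg_footprint_mm: tuple[float, float] | None = None,
) -> tuple[VOIMask, VOIMask]:
    """Construct the universal tumor (88 mm^3) and background (123 mm^3) VOIs.

    The target VOI surrounds the stereotactic inoculation coordinates; the
    background VOI sits in the tumor-free contralateral hemisphere. Both are
    box-shaped (see :func:`box_voi`); they must be disjoint and fully inside
    the grid.

    Returns
    -------
    (tumor_mask, background_mask)
        Achieved volumes are available as ``mask.volume_mm3``.
    """
    tumor = box_voi(geometry, tumor_center, tumor_volume_mm3, tumor_footprint_mm, "universal_tumor")
    bg = box_voi(geometry, bg_center, bg_volume_mm3, bg_footprint_mm, "background")
    if np.any(tumor.members & bg.members):
        raise GeometryError("universal tumor and background VOIs overlap")
    return tumor, bg
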