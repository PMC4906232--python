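"""Seeded synthetic mouse-head PET phantom and cohort generator.

The phantom emulates a reconstructed static [18F]-FET frame of an
orthotopic glioblastoma mouse: a uniform brain-sized background
compartment with uptake 1 (the reference), an ellipsoidal tumor at the
stereotactic inoculation site with a configurable tumor-to-background
uptake ratio, optional high-uptake extracerebral structures (Harderian
glands, a frontobasal skull hot spot for spill-in studies), anisotropic
Gaussian system blur, and pseudo-Poisson noise. The unblurred
piecewise-constant truth and per-structure masks are retained as ground
truth for every downstream stage.

The pipeline is a pure function of its spec and seed: the same spec and
seed always produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ActivityImage, GeometryError, ImageGeometry, RegionSet, VOIMask, make_universal_vois

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_GEOMETRY",
    "DEFAULT_FWHM",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomError",
    "default_spec",
    "generate_brain_phantom",
    "apply_psf",
    "add_noise",
    "generate_cohort",
    "default_universal_vois",
    "make_pvec_regions",
    "tumor_radius_for_volume",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Scanner point-spread function FWHM (mm), as measured for the small-animal
#: tomograph setup this toolkit models.
DEFAULT_FWHM = (1.20, 1.20, 1.72)

#: 96 x 96 x 64 crop of the 256 x 256 x 159 reconstruction grid at the native
#: 0.39 x 0.39 x 0.80 mm voxel size; keeps simulations fast while leaving wide
#: margins around the head structures.
DEFAULT_GEOMETRY = ImageGeometry(shape=(96, 96, 64), spacing=(0.39, 0.39, 0.80))

# Head-model layout (world offsets from the brain compartment center, mm).
BRAIN_SEMIAXES = (6.8, 8.5, 5.2)
TUMOR_OFFSET = (1.5, 1.0, 0.0)  # right hemisphere, slightly anterior
BG_VOI_OFFSET = (-2.9, 0.0, 0.0)  # tumor-free contralateral hemisphere
#: Thin-box in-plane footprint (mm) for the 123 mm^3 background VOI so it fits
#: wholly inside the contralateral hemisphere of the compartment.
BG_VOI_FOOTPRINT = (3.2, 7.0)
HARDERIAN_OFFSETS = ((-3.5, 9.5, -1.0), (3.5, 9.5, -1.0))
HARDERIAN_SEMIAXES = (1.2, 1.5, 1.0)
HARDERIAN_ACTIVITY = 3.0
SKULL_SPOT_OFFSET = (2.5, 7.8, -3.4)  # frontobasal, just outside the brain
SKULL_SPOT_SEMIAXES = (0.9, 0.9, 0.8)
SKULL_SPOT_ACTIVITY = 4.0


class PhantomError(ValueError):
    """Invalid phantom specification (overlap or boundary violation)."""


def tumor_radius_for_volume(volume_mm3: float) -> float:
    """Radius of a sphere with the given volume."""
    return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoidal structure with uniform activity."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    activity: float
    label: str = ""

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise PhantomError(f"structure '{self.label}': semi-axes must be > 0")

    def mask(self, geometry: ImageGeometry) -> np.ndarray:
        """Boolean grid of voxels whose centers fall inside the ellipsoid."""
        gx, gy, gz = geometry.world_grid()
        cx, cy, cz = self.center
        ax, ay, az = self.semiaxes
        return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic animal.

    ``tumor.activity`` is the tumor-to-background uptake ratio U >= 1
    (the brain compartment is the unit reference). ``noise_kappa`` scales
    pseudo-Poisson noise: voxel variance = kappa^2 * local mean.
    """

    geometry: ImageGeometry = DEFAULT_GEOMETRY
    brain: Ellipsoid = field(
        default=Ellipsoid(
            center=tuple(DEFAULT_GEOMETRY.index_to_world((np.array(DEFAULT_GEOMETRY.shape) - 1) / 2.0)),
            semiaxes=BRAIN_SEMIAXES,
            activity=1.0,
            label="brain",
        )
    )
    tumor: Ellipsoid = field(
        default=Ellipsoid(
            center=tuple(
                np.asarray(DEFAULT_GEOMETRY.index_to_world((np.array(DEFAULT_GEOMETRY.shape) - 1) / 2.0))
                + TUMOR_OFFSET
            ),
            semiaxes=(tumor_radius_for_volume(40.0),) * 3,
            activity=2.0,
            label="tumor",
        )
    )
    extracerebral: tuple[Ellipsoid, ...] = ()
    psf_fwhm: tuple[float, float, float] = DEFAULT_FWHM
    noise_kappa: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor.activity < 1.0:
            raise PhantomError("tumor uptake ratio U must be >= 1")
        if self.noise_kappa < 0:
            raise PhantomError("noise_kappa must be >= 0")
        if any(f < 0 for f in self.psf_fwhm):
            raise PhantomError("PSF FWHM must be >= 0 per axis")


def brain_center(geometry: ImageGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """World position of the grid center (the brain compartment center)."""
    return geometry.index_to_world((np.array(geometry.shape) - 1) / 2.0)


def default_spec(
    tumor_volume_mm3: float = 40.0,
    uptake_ratio: float = 2.0,
    geometry: ImageGeometry = DEFAULT_GEOMETRY,
    noise_kappa: float = 0.05,
    seed: int = 0,
    include_glands: bool = True,
    include_skull_spot: bool = False,
    psf_fwhm: tuple[float, float, float] = DEFAULT_FWHM,
) -> PhantomSpec:
    """Standard single-animal spec: spherical tumor at the stereotactic site.

    ``include_skull_spot`` adds a frontobasal bone hot spot (the structure
    responsible for occasional spill-in into the universal target VOI).
    """
    center = brain_center(geometry)
    radius = tumor_radius_for_volume(tumor_volume_mm3)
    extras: list[Ellipsoid] = []
    if include_glands:
        for i, off in enumerate(HARDERIAN_OFFSETS):
            extras.append(
                Ellipsoid(
                    center=tuple(center + off),
                    semiaxes=HARDERIAN_SEMIAXES,
                    activity=HARDERIAN_ACTIVITY,
                    label=f"harderian_{'left' if i == 0 else 'right'}",
                )
            )
    if include_skull_spot:
        extras.append(
            Ellipsoid(
                center=tuple(center + SKULL_SPOT_OFFSET),
                semiaxes=SKULL_SPOT_SEMIAXES,
                activity=SKULL_SPOT_ACTIVITY,
                label="skull_spot",
            )
        )
    return PhantomSpec(
        geometry=geometry,
        brain=Ellipsoid(tuple(center), BRAIN_SEMIAXES, 1.0, "brain"),
        tumor=Ellipsoid(tuple(center + TUMOR_OFFSET), (radius,) * 3, float(uptake_ratio), "tumor"),
        extracerebral=tuple(extras),
        psf_fwhm=psf_fwhm,
        noise_kappa=noise_kappa,
        seed=int(seed),
    )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom image."""

    truth: ActivityImage
    masks: dict[str, VOIMask]
    true_volume_mm3: float
    uptake_ratio: float
    seed: int


def _check_margin(members: np.ndarray, geometry: ImageGeometry, fwhm: Sequence[float], label: str) -> None:
    """Require >= 3 PSF sigmas between a structure and the grid boundary."""
    if not members.any():
        return
    margins = [
        int(np.ceil(3.0 * f * FWHM_TO_SIGMA / s)) for f, s in zip(fwhm, geometry.spacing)
    ]
    idx = np.nonzero(members)
    for axis in range(3):
        lo, hi = idx[axis].min(), idx[axis].max()
        if lo < margins[axis] or hi > geometry.shape[axis] - 1 - margins[axis]:
            raise PhantomError(
                f"structure '{label}' is closer than 3 PSF sigmas to the grid boundary"
            )


def _integrated_gaussian_kernel(sigma_vox: float, truncate: float = 6.0) -> np.ndarray:
    """1-D Gaussian kernel integrated over voxel extents (erf differences).

    Voxels integrate activity over their extent, so the correct discrete
    PSF weight of voxel offset k is the Gaussian mass of the interval
    [k - 1/2, k + 1/2] (in voxel units), not the sampled density. This
    makes cumulative sums of the kernel agree with the Gaussian CDF at
    voxel boundaries to machine precision, which the geometric transfer
    matrix relies on. The kernel is renormalized so blurring conserves
    total activity exactly away from the grid boundary.
    """
    from scipy.special import erf

    radius = max(1, int(np.ceil(truncate * sigma_vox)))
    edges = (np.arange(-radius, radius + 1 + 1) - 0.5) / (sigma_vox * np.sqrt(2.0))
    weights = 0.5 * np.diff(erf(edges))
    return weights / weights.sum()


def apply_psf(image: ActivityImage, fwhm: Sequence[float]) -> ActivityImage:
    """Blur with the separable Gaussian system PSF (zero-padded boundaries).

    sigma per axis is FWHM / (2 sqrt(2 ln 2)), discretized as the
    voxel-integrated Gaussian; total activity is conserved to within 0.1%
    whenever the support keeps the 3-sigma boundary margin.
    """
    fwhm = tuple(float(f) for f in fwhm)
    if any(f < 0 for f in fwhm):
        raise PhantomError("PSF FWHM must be >= 0 per axis")
    sigma_vox = [f * FWHM_TO_SIGMA / s for f, s in zip(fwhm, image.geometry.spacing)]
    blurred = image.values.copy()
    for axis, s in enumerate(sigma_vox):
        if s == 0:
            continue
        kernel = _integrated_gaussian_kernel(s)
        blurred = ndimage.correlate1d(blurred, kernel, axis=axis, mode="constant", cval=0.0)
    return ActivityImage(image.geometry, blurred)


def add_noise(image: ActivityImage, kappa: float, seed: int) -> ActivityImage:
    """Pseudo-Poisson noise: v -> max(0, v + N(0, kappa^2 * max(v, 0)))."""
    if kappa < 0:
        raise PhantomError("kappa must be >= 0")
    if kappa == 0:
        return ActivityImage(image.geometry, image.values.copy())
    rng = np.random.default_rng(seed)
    sd = kappa * np.sqrt(np.clip(image.values, 0.0, None))
    noisy = image.values + rng.standard_normal(image.values.shape) * sd
    return ActivityImage(image.geometry, np.clip(noisy, 0.0, None))


def generate_brain_phantom(spec: PhantomSpec) -> tuple[ActivityImage, PhantomTruth]:
    """Build the piecewise-constant truth, blur it, add noise.

    Paint order: brain, then extracerebral structures (which must not
    intersect the brain), then the tumor last (overwriting brain tissue).
    The returned truth image is the unblurred noiseless field.
    """
    geom = spec.geometry
    values = np.zeros(geom.shape, dtype=np.float64)
    masks: dict[str, VOIMask] = {}

    brain_m = spec.brain.mask(geom)
    if not brain_m.any():
        raise PhantomError("brain compartment contains no voxels")
    _check_margin(brain_m, geom, spec.psf_fwhm, "brain")
    values[brain_m] = spec.brain.activity
    masks["brain"] = VOIMask(geom, brain_m, "brain")

    for structure in spec.extracerebral:
        m = structure.mask(geom)
        if np.any(m & brain_m):
            raise PhantomError(f"extracerebral structure '{structure.label}' intersects the brain")
        _check_margin(m, geom, spec.psf_fwhm, structure.label or "extracerebral")
        values[m] = structure.activity
        masks[structure.label or f"extracerebral_{len(masks)}"] = VOIMask(geom, m, structure.label)

    tumor_m = spec.tumor.mask(geom)
    _check_margin(tumor_m, geom, spec.psf_fwhm, "tumor")
    values[tumor_m] = spec.tumor.activity
    masks["tumor"] = VOIMask(geom, tumor_m, "tumor")

    truth_img = ActivityImage(geom, values)
    blurred = apply_psf(truth_img, spec.psf_fwhm)
    observed = add_noise(blurred, spec.noise_kappa, spec.seed)
    truth = PhantomTruth(
        truth=truth_img,
        masks=masks,
        true_volume_mm3=masks["tumor"].volume_mm3,
        uptake_ratio=spec.tumor.activity,
        seed=spec.seed,
    )
    return observed, truth


def generate_cohort(
    n: int,
    volume_range_mm3: tuple[float, float] = (5.0, 150.0),
    uptake_range: tuple[float, float] = (1.3, 3.5),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    **spec_kwargs,
) -> tuple[list[tuple[ActivityImage, PhantomTruth]], pd.DataFrame]:
    """Generate ``n`` phantoms with uniformly drawn tumor volumes and ratios.

    Mirrors the two-round animal-study design (8 calibration + 15
    validation tumors); volumes span the range observed histologically
    (a few to ~150 mm^3) and uptake ratios the plausible FET contrast
    range. Returns the cohort and a truth table with one row per animal.
    """
    if n < 1:
        raise PhantomError("cohort size must be >= 1")
    lo_v, hi_v = volume_range_mm3
    lo_u, hi_u = uptake_range
    if not (0 < lo_v <= hi_v) or not (1.0 <= lo_u <= hi_u):
        raise PhantomError("invalid volume or uptake range")
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(lo_v, hi_v, size=n)
    uptakes = rng.uniform(lo_u, hi_u, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    cohort: list[tuple[ActivityImage, PhantomTruth]] = []
    rows = []
    for i in range(n):
        if base_spec is not None:
            radius = tumor_radius_for_volume(volumes[i])
            spec = replace(
                base_spec,
                tumor=replace(base_spec.tumor, semiaxes=(radius,) * 3, activity=float(uptakes[i])),
                seed=int(child_seeds[i]),
            )
        else:
            spec = default_spec(
                tumor_volume_mm3=float(volumes[i]),
                uptake_ratio=float(uptakes[i]),
                seed=int(child_seeds[i]),
                **spec_kwargs,
            )
        image, truth = generate_brain_phantom(spec)
        cohort.append((image, truth))
        rows.append(
            {
                "id": i,
                "true_volume_mm3": truth.true_volume_mm3,
                "uptake_ratio": truth.uptake_ratio,
                "seed": int(child_seeds[i]),
            }
        )
    return cohort, pd.DataFrame(rows)


def default_universal_vois(geometry: ImageGeometry = DEFAULT_GEOMETRY) -> tuple[VOIMask, VOIMask]:
    """Universal 88 mm^3 tumor and 123 mm^3 background VOIs at the default
    stereotactic and contralateral positions of the head model."""
    center = brain_center(geometry)
    return make_universal_vois(
        geometry,
        tumor_center=tuple(center + TUMOR_OFFSET),
        bg_center=tuple(center + BG_VOI_OFFSET),
        bg_footprint_mm=BG_VOI_FOOTPRINT,
    )


def make_pvec_regions(
    truth: PhantomTruth,
    tumor_region: VOIMask | None = None,
) -> RegionSet:
    """Eight-region mask for partial-volume correction.

    Regions: individual tumor VOI (defaults to the true tumor mask, or the
    'optimal' individual BTV when provided), rest of cerebrum, left/right
    Harderian glands, and four extracerebral boxes (frontal, spinal,
    superior, basal). Together they cover all activity of the default
    phantom; voxels outside every region are treated as zero activity.
    """
    geom = truth.truth.geometry
    center = brain_center(geom)
    gx, gy, gz = geom.world_grid()
    rx, ry, rz = gx - center[0], gy - center[1], gz - center[2]

    brain = truth.masks["brain"].members
    tumor = (tumor_region.members & brain) if tumor_region is not None else truth.masks["tumor"].members
    if not tumor.any():
        raise GeometryError("tumor region of the PVEC mask is empty")
    cerebrum = brain & ~tumor

    gland_l = truth.masks.get("harderian_left")
    gland_r = truth.masks.get("harderian_right")
    gland_l_m = gland_l.members if gland_l is not None else np.zeros(geom.shape, bool)
    gland_r_m = gland_r.members if gland_r is not None else np.zeros(geom.shape, bool)

    taken = brain | gland_l_m | gland_r_m
    frontal = ((ry >= 8.8) & (ry <= 12.5) & (np.abs(rx) <= 6.0) & (np.abs(rz) <= 4.0)) & ~taken
    spinal = ((ry <= -8.8) & (ry >= -12.5) & (np.abs(rx) <= 6.0) & (np.abs(rz) <= 4.0)) & ~taken
    superior = ((rz >= 5.5) & (rz <= 8.5) & (np.abs(rx) <= 6.8) & (np.abs(ry) <= 8.5)) & ~taken
    basal = ((rz <= -5.5) & (rz >= -8.5) & (np.abs(rx) <= 6.8) & (np.abs(ry) <= 8.5)) & ~taken

    named = [
        ("tumor", tumor),
        ("cerebrum", cerebrum),
        ("harderian_left", gland_l_m),
        ("harderian_right", gland_r_m),
        ("frontal", frontal),
        ("spinal", spinal),
        ("superior", superior),
        ("basal", basal),
    ]
    regions = [(label, VOIMask(geom, m, label)) for label, m in named if m.any()]
    return RegionSet(geom, regions)
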