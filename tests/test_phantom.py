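from dataclasses import replace

import numpy as np
import pytest

from fetquant.geometry import ActivityImage, ImageGeometry, box_voi
from fetquant.phantom import (
    FWHM_TO_SIGMA,
    PhantomError,
    add_noise,
    apply_psf,
    brain_center,
    default_spec,
    generate_brain_phantom,
    generate_cohort,
)
from fetquant.quant import region_uptake_stats


def test_same_seed_bit_identical_different_seed_differs():
    spec = default_spec(30.0, 2.0, seed=7)
    img_a, _ = generate_brain_phantom(spec)
    img_b, _ = generate_brain_phantom(spec)
    assert np.array_equal(img_a.values, img_b.values)
    img_c, _ = generate_brain_phantom(replace(spec, seed=8))
    assert not np.array_equal(img_a.values, img_c.values)


def test_true_volume_matches_voxel_center_count_oracle():
    """Tumor volume is the count of voxel centers inside the analytic
    ellipsoid; for semi-axes 2.76 mm the discretized volume sits close to
    the continuous (4/3) pi r^3 = 88.05 mm^3."""
    spec = default_spec(40.0, 2.0, noise_kappa=0.0)
    spec = replace(spec, tumor=replace(spec.tumor, semiaxes=(2.76, 2.76, 2.76)))
    _, truth = generate_brain_phantom(spec)

    geom = truth.truth.geometry
    gx, gy, gz = geom.world_grid()
    cx, cy, cz = spec.tumor.center
    inside = ((gx - cx) / 2.76) ** 2 + ((gy - cy) / 2.76) ** 2 + ((gz - cz) / 2.76) ** 2 <= 1.0
    assert truth.true_volume_mm3 == pytest.approx(inside.sum() * geom.voxel_volume_mm3, abs=0)
    analytic = 4.0 / 3.0 * np.pi * 2.76**3
    assert truth.true_volume_mm3 == pytest.approx(analytic, abs=0.5)


def test_invisible_tumor_when_ratio_is_one():
    """U = 1, no extracerebral structures, no noise: deep inside the brain
    the blurred image is uniform and SUV ratios are 1."""
    spec = default_spec(40.0, 1.0, noise_kappa=0.0, include_glands=False)
    image, _ = generate_brain_phantom(spec)
    center = brain_center()
    target = box_voi(image.geometry, tuple(center), 2.0, label="t")
    background = box_voi(image.geometry, tuple(center + (-2.0, 0.0, 0.0)), 2.0, label="b")
    stats = region_uptake_stats(image, target, background)
    assert stats.suv_max_bg == pytest.approx(1.0, abs=1e-6)
    assert stats.suv_mean_bg == pytest.approx(1.0, abs=1e-6)


def test_structure_near_boundary_rejected():
    spec = default_spec(30.0, 2.0)
    bad_tumor = replace(spec.tumor, center=(1.0, 1.0, 1.0))
    with pytest.raises(PhantomError, match="boundary"):
        generate_brain_phantom(replace(spec, tumor=bad_tumor))


def test_extracerebral_structure_may_not_intersect_brain():
    spec = default_spec(30.0, 2.0, include_glands=True)
    bad = replace(spec.extracerebral[0], center=spec.brain.center)
    with pytest.raises(PhantomError, match="intersects the brain"):
        generate_brain_phantom(replace(spec, extracerebral=(bad,)))


class TestApplyPsf:
    def test_zero_fwhm_is_identity(self):
        geom = ImageGeometry((8, 8, 8), (1, 1, 1))
        rng = np.random.default_rng(0)
        image = ActivityImage(geom, rng.random(geom.shape))
        out = apply_psf(image, (0.0, 0.0, 0.0))
        assert np.array_equal(out.values, image.values)

    def test_negative_fwhm_rejected(self):
        geom = ImageGeometry((8, 8, 8), (1, 1, 1))
        image = ActivityImage(geom, np.ones(geom.shape))
        with pytest.raises(PhantomError):
            apply_psf(image, (-1.0, 0.0, 0.0))

    def test_point_source_matches_integrated_gaussian_closed_form(self):
        """A blurred delta reproduces the separable voxel-integrated
        Gaussian (erf differences) evaluated on the grid."""
        from scipy.special import erf

        geom = ImageGeometry((33, 33, 33), (0.39, 0.39, 0.80))
        delta = np.zeros(geom.shape)
        delta[16, 16, 16] = 1.0
        blurred = apply_psf(ActivityImage(geom, delta), (1.2, 1.2, 1.72)).values

        sigmas = np.array([1.2, 1.2, 1.72]) * FWHM_TO_SIGMA
        assert sigmas[0] == pytest.approx(0.5096, abs=1e-4)
        assert sigmas[2] == pytest.approx(0.7304, abs=1e-4)

        def profile(n, h, s):
            k = (np.arange(n) - 16) * h
            w = 0.5 * (erf((k + h / 2) / (s * np.sqrt(2))) - erf((k - h / 2) / (s * np.sqrt(2))))
            return w / w.sum()

        analytic = (
            profile(33, 0.39, sigmas[0])[:, None, None]
            * profile(33, 0.39, sigmas[1])[None, :, None]
            * profile(33, 0.80, sigmas[2])[None, None, :]
        )
        significant = analytic > 1e-6 * analytic.max()
        rel = np.abs(blurred - analytic)[significant] / analytic[significant]
        assert rel.max() < 1e-4

    def test_total_activity_conserved(self, unblurred_phantom):
        image, _ = unblurred_phantom
        blurred = apply_psf(image, (1.2, 1.2, 1.72))
        loss = abs(blurred.values.sum() - image.values.sum()) / image.values.sum()
        assert loss <= 1e-3

    def test_partial_volume_loss_grows_as_tumor_shrinks(self):
        """Blurred peak < true activity for small hot structures, and the
        loss increases monotonically as the structure shrinks."""
        peaks = []
        for volume in (8.0, 20.0, 60.0):
            image, truth = generate_brain_phantom(default_spec(volume, 2.0, noise_kappa=0.0))
            peaks.append(image.values[truth.masks["tumor"].members].max())
        assert all(p < 2.0 for p in peaks)
        assert peaks[0] < peaks[1] < peaks[2]


class TestAddNoise:
    def test_kappa_zero_is_identity(self):
        geom = ImageGeometry((8, 8, 8), (1, 1, 1))
        image = ActivityImage(geom, np.full(geom.shape, 2.0))
        assert np.array_equal(add_noise(image, 0.0, 0).values, image.values)

    def test_moments_match_model(self):
        geom = ImageGeometry((100, 100, 100), (1, 1, 1))
        image = ActivityImage(geom, np.ones(geom.shape))
        noisy = add_noise(image, 0.1, seed=123)
        assert abs(noisy.values.mean() - 1.0) < 3e-4
        assert abs(noisy.values.std() - 0.1) / 0.1 < 0.02

    def test_two_seeds_differ_but_share_statistics(self):
        geom = ImageGeometry((50, 50, 50), (1, 1, 1))
        image = ActivityImage(geom, np.ones(geom.shape))
        a = add_noise(image, 0.1, seed=1)
        b = add_noise(image, 0.1, seed=2)
        assert not np.array_equal(a.values, b.values)
        assert abs(a.values.mean() - b.values.mean()) < 1e-3
        assert abs(a.values.std() - b.values.std()) < 1e-3

    def test_values_clamped_non_negative(self):
        geom = ImageGeometry((30, 30, 30), (1, 1, 1))
        image = ActivityImage(geom, np.full(geom.shape, 1e-4))
        noisy = add_noise(image, 5.0, seed=0)
        assert noisy.values.min() >= 0.0


class TestCohort:
    def test_cardinality_and_truth_table(self):
        cohort, table = generate_cohort(4, (20.0, 60.0), (1.5, 2.5), seed=3)
        assert len(cohort) == 4
        assert len(table) == 4
        assert set(table.columns) == {"id", "true_volume_mm3", "uptake_ratio", "seed"}

    def test_degenerate_volume_range_gives_equal_volumes(self):
        _, table = generate_cohort(3, (40.0, 40.0), (2.0, 2.0), seed=3)
        vols = table["true_volume_mm3"].to_numpy()
        # all identical up to voxel discretization (identical tumor spec)
        assert np.ptp(vols) == 0.0
        assert vols[0] == pytest.approx(40.0, abs=1.0)

    def test_draws_respect_ranges(self):
        _, table = generate_cohort(12, (5.0, 150.0), (1.3, 3.5), seed=9)
        assert table["true_volume_mm3"].between(4.0, 151.0).all()
        assert table["uptake_ratio"].between(1.3, 3.5).all()

    def test_same_seed_reproduces_cohort(self):
        _, t1 = generate_cohort(3, (20.0, 60.0), (1.5, 2.5), seed=5)
        _, t2 = generate_cohort(3, (20.0, 60.0), (1.5, 2.5), seed=5)
        assert t1.equals(t2)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(PhantomError):
            generate_cohort(2, (0.0, 50.0), (1.5, 2.0), seed=0)
        with pytest.raises(PhantomError):
            generate_cohort(0, (10.0, 50.0), (1.5, 2.0), seed=0)
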