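import numpy as np
import pytest
from scipy import ndimage, stats

from fetquant.btv import (
    BTVError,
    CalibrationModel,
    STANDARD_THRESHOLDS,
    ThresholdPlausibilityWarning,
    default_calibration,
    find_optimal_threshold,
    fit_calibration,
    predict_threshold,
    rms_percent_error,
    segment_btv,
    volume_threshold_curve,
)
from fetquant.geometry import ActivityImage, ImageGeometry, VOIMask
from fetquant.pipeline import default_search_region


def _random_instance(seed, shape=(32, 32, 32)):
    """Smooth random image with a central search region."""
    rng = np.random.default_rng(seed)
    geom = ImageGeometry(shape, (1, 1, 1))
    values = ndimage.gaussian_filter(rng.random(shape), 2.0) + 0.5
    image = ActivityImage(geom, values)
    region = np.zeros(shape, bool)
    region[8:24, 8:24, 8:24] = True
    return image, VOIMask(geom, region, "search"), rng


class TestSegmentBtv:
    def test_threshold_above_max_gives_empty(self):
        image, region, _ = _random_instance(0)
        result = segment_btv(image, 1.0, image.values.max() * 2, region)
        assert result.volume_mm3 == 0.0

    def test_unblurred_phantom_recovers_true_mask(self, unblurred_phantom, universal_vois):
        image, truth = unblurred_phantom
        tumor_voi, _ = universal_vois
        search = default_search_region(tumor_voi)
        result = segment_btv(image, 1.0, 1.5, search, "hot-connected")
        assert np.array_equal(result.mask.members, truth.masks["tumor"].members)
        assert result.volume_mm3 == pytest.approx(truth.true_volume_mm3, abs=0)

    @pytest.mark.parametrize("mode", ["hot-connected", "all-voxels"])
    def test_nestedness_across_thresholds(self, blurred_phantom, universal_vois, mode):
        image, _ = blurred_phantom
        tumor_voi, bg_voi = universal_vois
        bg_mean = float(image.values[bg_voi.members].mean())
        search = default_search_region(tumor_voi)
        previous = None
        for theta in STANDARD_THRESHOLDS:
            mask = segment_btv(image, bg_mean, theta, search, mode).mask.members
            if previous is not None:
                assert np.all(mask <= previous)  # subset of the lower threshold
            previous = mask

    def test_invalid_inputs(self):
        image, region, _ = _random_instance(0)
        with pytest.raises(BTVError):
            segment_btv(image, 0.0, 1.4, region)
        with pytest.raises(BTVError):
            segment_btv(image, 1.0, 1.4, region, mode="bogus")


class TestVolumeThresholdCurve:
    def test_constant_image_step_at_equality(self):
        geom = ImageGeometry((10, 10, 10), (1, 1, 1))
        image = ActivityImage(geom, np.ones(geom.shape))
        region = VOIMask(geom, np.ones(geom.shape, bool), "all")
        curve = volume_threshold_curve(image, 1.0, region, [0.5, 1.0, 1.5], "all-voxels")
        volumes = [v for _, v in curve]
        assert volumes == [1000.0, 1000.0, 0.0]  # >= comparison includes equality

    def test_single_hot_voxel_step_function(self):
        geom = ImageGeometry((10, 10, 10), (1, 1, 1))
        values = np.ones(geom.shape)
        values[5, 5, 5] = 5.0
        image = ActivityImage(geom, values)
        region = VOIMask(geom, np.ones(geom.shape, bool), "all")
        curve = volume_threshold_curve(image, 1.0, region, [2.0, 5.0, 6.0], "hot-connected")
        assert [v for _, v in curve] == [1.0, 1.0, 0.0]

    def test_unsorted_thresholds_rejected(self):
        image, region, _ = _random_instance(0)
        with pytest.raises(BTVError):
            volume_threshold_curve(image, 1.0, region, [1.6, 1.4])

    @pytest.mark.parametrize("seed", range(5))
    def test_curve_non_increasing_on_random_images(self, seed):
        image, region, rng = _random_instance(seed)
        thresholds = np.sort(rng.uniform(0.5, 1.5, size=8))
        curve = volume_threshold_curve(image, 1.0, region, thresholds, "hot-connected")
        volumes = [v for _, v in curve]
        assert all(b <= a for a, b in zip(volumes, volumes[1:]))


def brute_force_optimal(image, bg_mean, reference, region, mode):
    """Independent enumeration: try every candidate threshold via
    segment_btv and track the best |volume - reference| with the
    smaller-threshold tie-break."""
    candidates = sorted(set(image.values[region.members] / bg_mean)) + [
        image.values[region.members].max() / bg_mean * 1.5
    ]
    best = None
    for theta in candidates:
        if theta <= 0:
            continue
        volume = segment_btv(image, bg_mean, theta, region, mode).volume_mm3
        err = abs(volume - reference)
        if best is None or err < best[1] - 1e-12:
            best = (theta, err, volume)
    return best


class TestFindOptimalThreshold:
    def test_exact_recovery_on_unblurred_phantom(self, unblurred_phantom, universal_vois):
        image, truth = unblurred_phantom
        tumor_voi, bg_voi = universal_vois
        bg_mean = float(image.values[bg_voi.members].mean())
        search = default_search_region(tumor_voi)
        theta, result = find_optimal_threshold(
            image, bg_mean, truth.true_volume_mm3, search
        )
        assert result.volume_mm3 == pytest.approx(truth.true_volume_mm3, abs=0)
        assert 1.0 < theta <= 2.0

    @pytest.mark.parametrize("mode", ["hot-connected", "all-voxels"])
    def test_matches_brute_force_enumeration(self, mode):
        image, region, rng = _random_instance(1)
        reference = 150.0
        theta, result = find_optimal_threshold(image, 1.0, reference, region, mode)
        bf_theta, bf_err, bf_volume = brute_force_optimal(image, 1.0, reference, region, mode)
        assert theta == pytest.approx(bf_theta, rel=1e-12)
        assert result.volume_mm3 == bf_volume

    def test_sub_voxel_reference_warns(self):
        image, region, _ = _random_instance(2)
        with pytest.warns(UserWarning, match="smaller than one voxel"):
            find_optimal_threshold(image, 1.0, 0.5, region)

    def test_invalid_reference_rejected(self):
        image, region, _ = _random_instance(0)
        with pytest.raises(BTVError):
            find_optimal_threshold(image, 1.0, 0.0, region)


class TestCalibration:
    def test_collinear_points_recover_published_coefficients(self):
        x = np.array([1.5, 1.9, 2.3, 2.8, 3.2])
        pairs = list(zip(x, 0.3215 * x + 0.5654))
        model = fit_calibration(pairs)
        assert model.slope == pytest.approx(0.3215, abs=1e-12)
        assert model.intercept == pytest.approx(0.5654, abs=1e-12)
        assert model.pearson_rho == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope_and_rho(self):
        model = fit_calibration([(1.5, 1.4), (2.0, 1.4), (2.5, 1.4)])
        assert model.slope == 0.0
        assert model.pearson_rho == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(BTVError):
            fit_calibration([(2.0, 1.2), (2.0, 1.3), (2.0, 1.4)])

    def test_monte_carlo_slope_recovery(self):
        """OLS is unbiased: over replicated noisy calibration rounds the
        mean slope estimate approaches the generating slope."""
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(200):
            x = rng.uniform(1.3, 3.5, size=8)
            y = 0.32 * x + 0.57 + rng.normal(0.0, 0.03, size=8)
            slopes.append(fit_calibration(list(zip(x, y))).slope)
        assert abs(np.mean(slopes) - 0.32) < 0.01


class TestPredictThreshold:
    def test_published_equation_at_x_two(self):
        assert predict_threshold(2.0, default_calibration()) == 0.3215 * 2.0 + 0.5654
        assert predict_threshold(2.0) == pytest.approx(1.2084, abs=1e-12)

    def test_zero_x_returns_intercept(self):
        model = CalibrationModel(0.5, 1.3)
        assert predict_threshold(0.0, model) == pytest.approx(1.3)

    def test_plausibility_warning_below_background(self):
        # 0.3215 x + 0.5654 = 1 at x ~ 1.3518; below that the prediction
        # is not a plausible tumor/background separation
        with pytest.warns(ThresholdPlausibilityWarning):
            y = predict_threshold(1.35, default_calibration())
        assert y == pytest.approx(0.9994, abs=1e-4)


@pytest.mark.parametrize(
    "est,ref,expected",
    [
        ([10.0, 20.0], [10.0, 20.0], 0.0),
        ([20.0, 0.0], [10.0, 10.0], 100.0),  # errors +100% and -100%
        ([30.0], [10.0], 200.0),
    ],
)
def test_rms_percent_error(est, ref, expected):
    assert rms_percent_error(est, ref) == pytest.approx(expected)


def test_rms_percent_error_rejects_empty_and_nonpositive():
    with pytest.raises(BTVError):
        rms_percent_error([], [])
    with pytest.raises(BTVError):
        rms_percent_error([1.0], [0.0])
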