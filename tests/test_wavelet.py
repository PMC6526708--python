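"""À trous decomposition, noise estimation and puncta detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import punctakit as pk
from punctakit.simulate import _gaussian_patch

from oracles import atrous_planes_direct, scale1_noise_gain


class TestAtrousDecomposition:
    def test_constant_frame_has_zero_detail(self):
        frame = np.full((32, 32), 7.5)
        d = pk.atrous_decompose(frame, 3)
        for plane in d.detail_planes:
            assert np.allclose(plane, 0.0, atol=1e-12)
        assert np.allclose(d.residual, 7.5)

    def test_unit_impulse_center_value(self):
        # center detail value = 1 - (6/16)^2 for the separable B3 kernel
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        d = pk.atrous_decompose(frame, 1)
        assert d.detail_planes[0][16, 16] == pytest.approx(0.859375, abs=1e-12)

    def test_reconstruction_identity_random_frames(self, rng):
        for _ in range(10):
            frame = rng.uniform(0, 1000, size=(64, 64))
            d = pk.atrous_decompose(frame, 4)
            err = np.abs(d.reconstruct() - frame).max()
            assert err < 1e-9

    @pytest.mark.parametrize("n_scales", [1, 2, 3])
    def test_matches_direct_dilated_convolution_oracle(self, rng, n_scales):
        frame = rng.uniform(0, 100, size=(40, 40))
        d = pk.atrous_decompose(frame, n_scales)
        planes, residual = atrous_planes_direct(frame, n_scales)
        for mine, ref in zip(d.detail_planes, planes):
            assert np.abs(mine - ref).max() < 1e-10
        assert np.abs(d.residual - residual).max() < 1e-10

    def test_too_deep_decomposition_rejected(self):
        with pytest.raises(ValueError):
            pk.atrous_decompose(np.zeros((16, 16)), 5)

    def test_non_finite_frame_rejected(self):
        frame = np.zeros((16, 16))
        frame[3, 3] = np.nan
        with pytest.raises(ValueError):
            pk.atrous_decompose(frame, 2)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        h=st.integers(16, 48),
        w=st.integers(16, 48),
        n_scales=st.integers(1, 4),
    )
    def test_reconstruction_identity_property(self, seed, h, w, n_scales):
        frame = np.random.default_rng(seed).normal(100, 30, size=(h, w))
        d = pk.atrous_decompose(frame, n_scales)
        assert np.abs(d.reconstruct() - frame).max() < 1e-9


class TestNoiseEstimate:
    def test_all_zero_plane(self):
        assert pk.estimate_plane_noise(np.zeros((16, 16))) == 0.0

    def test_gaussian_plane_matches_analytic_filter_gain(self, rng):
        sigma = 2.0
        plane = rng.normal(0, sigma, size=(256, 256))
        w1 = pk.atrous_decompose(plane, 1).detail_planes[0]
        expected = sigma * scale1_noise_gain()
        assert pk.estimate_plane_noise(w1) == pytest.approx(expected, rel=0.05)

    def test_robust_to_sparse_outliers(self, rng):
        plane = rng.normal(0, 1.0, size=(128, 128))
        clean = pk.estimate_plane_noise(plane)
        contaminated = plane.copy()
        idx = rng.choice(plane.size, size=plane.size // 100, replace=False)
        contaminated.ravel()[idx] += 100.0
        assert pk.estimate_plane_noise(contaminated) == pytest.approx(clean, rel=0.10)


def _render_spot_frame(x, y, sigma=1.3, amplitude=50.0, background=10.0,
                       shape=(64, 64), noise_sigma=1.0, seed=0):
    frame = np.full(shape, background)
    ys, xs, patch = _gaussian_patch(x, y, sigma, amplitude, shape)
    frame[ys, xs] += patch
    if noise_sigma:
        frame += np.random.default_rng(seed).normal(0, noise_sigma, shape)
    return np.clip(frame, 0, None)


class TestSignificanceSupport:
    def test_zero_frame_gives_empty_support(self):
        d = pk.atrous_decompose(np.zeros((64, 64)), 3)
        support = pk.significance_support(d, pk.DetectionParams())
        assert not support.any()

    def test_pure_noise_support_is_sparse(self, rng):
        frame = rng.normal(100, 5, size=(128, 128))
        d = pk.atrous_decompose(frame, 3)
        support = pk.significance_support(d, pk.DetectionParams())
        assert support.mean() < 0.005

    def test_bright_spot_support_contains_peak(self):
        frame = _render_spot_frame(30.0, 20.0, amplitude=100.0, noise_sigma=2.0)
        d = pk.atrous_decompose(frame, 3)
        support = pk.significance_support(d, pk.DetectionParams())
        assert support[20, 30]
        from scipy import ndimage
        _, n = ndimage.label(support, structure=np.ones((3, 3)))
        assert n == 1

    def test_empty_detection_scales_rejected(self):
        d = pk.atrous_decompose(np.zeros((32, 32)), 3)
        with pytest.raises(ValueError):
            pk.significance_support(d, pk.DetectionParams(detection_scales=frozenset()))

    def test_support_monotone_in_k_sigma(self, rng):
        frame = rng.normal(100, 5, size=(96, 96))
        frame += _render_spot_frame(40, 40, noise_sigma=0.0, background=0.0,
                                    shape=(96, 96))
        d = pk.atrous_decompose(frame, 3)
        prev = None
        for k in (1.0, 2.0, 3.0, 5.0):
            sup = pk.significance_support(d, pk.DetectionParams(k_sigma=k))
            if prev is not None:
                assert not (sup & ~prev).any()  # support only shrinks
            prev = sup

    @pytest.mark.parametrize("scale_factor", [0.1, 1.0, 250.0])
    def test_support_invariant_to_intensity_scaling(self, rng, scale_factor):
        frame = _render_spot_frame(25.5, 40.2, noise_sigma=2.0)
        params = pk.DetectionParams()
        ref = pk.significance_support(pk.atrous_decompose(frame, 3), params)
        scaled = pk.significance_support(
            pk.atrous_decompose(frame * scale_factor, 3), params
        )
        assert np.array_equal(ref, scaled)


class TestDetectFrame:
    def test_two_well_separated_spots(self):
        frame = np.full((64, 64), 10.0)
        for x, y in [(20.3, 30.7), (30.3, 30.7)]:
            ys, xs, patch = _gaussian_patch(x, y, 1.3, 80.0, frame.shape)
            frame[ys, xs] += patch
        frame += np.random.default_rng(1).normal(0, 2.0, frame.shape)
        frame = np.clip(frame, 0, None)
        _, table = pk.detect_frame(frame, pk.DetectionParams(), 0.13)
        assert len(table) == 2
        found = sorted(zip(table.x_px, table.y_px))
        for (fx, fy), (tx, ty) in zip(found, [(20.3, 30.7), (30.3, 30.7)]):
            assert np.hypot(fx - tx, fy - ty) <= 0.5

    def test_blank_noise_frame_yields_no_puncta(self, rng):
        frame = np.clip(rng.normal(100, 5, size=(128, 128)), 0, None)
        _, table = pk.detect_frame(frame, pk.DetectionParams(), 0.13)
        # allow <=0.01 false puncta/µm² at defaults
        area_um2 = 128 * 128 * 0.13**2
        assert len(table) / area_um2 <= 0.01

    def test_min_area_filters_tiny_support(self):
        frame = _render_spot_frame(32, 32, sigma=0.6, amplitude=60, noise_sigma=1.0)
        params = pk.DetectionParams(min_area_px=4)
        _, small = pk.detect_frame(frame, params, 0.13)
        big = pk.DetectionParams(min_area_px=500)
        _, none = pk.detect_frame(frame, big, 0.13)
        assert len(none) == 0


class TestDetectStack:
    def test_persistent_spot_detected_every_frame(self):
        frames = np.stack([
            _render_spot_frame(40.4, 25.6, amplitude=90, noise_sigma=2.0, seed=s)
            for s in range(10)
        ])
        movie = pk.Movie(frames, 0.13, 1.0)
        det = pk.detect_stack(movie)
        assert len(det.puncta) == 10
        assert sorted(det.puncta.frame) == list(range(10))
        err = np.hypot(det.puncta.x_px - 40.4, det.puncta.y_px - 25.6)
        assert (err <= 0.5).all()

    def test_all_zero_movie(self):
        movie = pk.Movie(np.zeros((3, 32, 32)), 0.13, 1.0)
        det = pk.detect_stack(movie)
        assert len(det.puncta) == 0
        assert not det.masks.any()

    def test_recall_precision_on_default_simulation(self, small_movie_pair,
                                                    small_detections,
                                                    default_small_params):
        _, _, gt = small_movie_pair
        det_a, _ = small_detections
        m = pk.evaluate_detection(det_a, gt, default_small_params, pk.CHANNEL_A)
        assert m.recall >= 0.9
        assert m.precision >= 0.9
        assert m.centroid_rmse_px <= 0.5
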