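"""ROI construction, trace extraction, temporal lag and density analyses."""

import numpy as np
import pytest

import punctakit as pk
from punctakit.kinetics import RoiTrace

from oracles import xcorr_naive


def _movie(frames, dt=1.0, px=0.13):
    return pk.Movie(np.asarray(frames, float), px, dt)


class TestBuildRois:
    def test_empty_stacks_give_no_rois(self):
        empty = np.zeros((5, 32, 32), bool)
        assert pk.build_rois(empty, empty).n_rois == 0

    def test_cooccupied_site_becomes_one_roi(self):
        a = np.zeros((4, 32, 32), bool)
        b = np.zeros((4, 32, 32), bool)
        a[0, 10:14, 10:14] = True
        b[3, 10:14, 10:14] = True  # different frames, same site
        rois = pk.build_rois(a, b)
        assert rois.n_rois == 1
        assert rois.areas_px[1] == 16

    def test_single_channel_site_is_eliminated(self):
        a = np.zeros((4, 32, 32), bool)
        b = np.zeros((4, 32, 32), bool)
        a[:, 5:9, 5:9] = True
        assert pk.build_rois(a, b).n_rois == 0

    def test_argument_order_invariant(self, rng):
        a = rng.random((6, 48, 48)) > 0.95
        b = rng.random((6, 48, 48)) > 0.95
        r1 = pk.build_rois(a, b)
        r2 = pk.build_rois(b, a)
        assert np.array_equal(r1.label_map, r2.label_map)

    def test_ids_in_raster_order_and_min_area(self):
        a = np.zeros((1, 32, 32), bool)
        a[0, 20:24, 2:6] = True    # later in raster order
        a[0, 2:6, 10:14] = True    # earlier (smaller row)
        a[0, 10, 20] = True        # single pixel, below min_area
        rois = pk.build_rois(a, a, min_area_px=4)
        assert rois.n_rois == 2
        ys1, _ = rois.pixels(1)
        ys2, _ = rois.pixels(2)
        assert ys1.min() < ys2.min()


class TestExtractTraces:
    def test_uniform_movie_gives_constant_traces(self):
        a = np.zeros((3, 16, 16), bool)
        a[:, 4:8, 4:8] = True
        rois = pk.build_rois(a, a)
        m = _movie(np.full((3, 16, 16), 7.0))
        traces = pk.extract_traces(rois, m, m)
        assert len(traces) == 1
        assert np.allclose(traces[0].intensity_ref, 7.0)
        assert np.allclose(traces[0].intensity_query, 7.0)
        assert np.allclose(traces[0].t_s, [0, 1, 2])

    def test_single_pixel_roi_reproduces_pixel_series(self):
        masks = np.zeros((5, 16, 16), bool)
        masks[:, 3, 4] = True
        rois = pk.build_rois(masks, masks, min_area_px=1)
        frames = np.random.default_rng(0).random((5, 16, 16))
        m = _movie(frames)
        (trace,) = pk.extract_traces(rois, m, m)
        assert np.array_equal(trace.intensity_ref, frames[:, 3, 4])

    def test_calibration_mismatch_rejected(self):
        masks = np.zeros((2, 16, 16), bool)
        masks[:, 2:6, 2:6] = True
        rois = pk.build_rois(masks, masks)
        m1 = _movie(np.zeros((2, 16, 16)), dt=1.0)
        m2 = _movie(np.zeros((2, 16, 16)), dt=2.0)
        with pytest.raises(ValueError):
            pk.extract_traces(rois, m1, m2)


def _pulse_trace(onset, width, n=60, amp=10.0, lag=0):
    ref = np.ones(n)
    ref[onset : onset + width] += amp
    query = np.ones(n)
    query[onset + lag : onset + lag + width] += amp
    return RoiTrace(1, np.arange(n, dtype=float), ref, query, 1.0)


class TestTemporalCrossCorrelation:
    def test_identical_traces_peak_at_zero_with_r_one(self):
        tr = _pulse_trace(20, 10)
        lags, r = pk.temporal_cross_correlation(tr, max_lag_frames=8)
        assert r[lags == 0][0] == pytest.approx(1.0, abs=1e-9)
        assert lags[np.argmax(r)] == 0

    def test_delayed_query_peaks_at_positive_lag(self):
        # query(t) = ref(t - 2): reference precedes → peak at +2 frames
        tr = _pulse_trace(20, 10, lag=2)
        lags, r = pk.temporal_cross_correlation(tr, max_lag_frames=8)
        assert lags[np.argmax(r)] == 2.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            ref = rng.random(80)
            query = rng.random(80)
            tr = RoiTrace(1, np.arange(80.0), ref, query, 1.0)
            lags, r = pk.temporal_cross_correlation(tr, max_lag_frames=10)
            lags_o, r_o = xcorr_naive(ref, query, 10)
            assert np.abs(r - r_o).max() < 1e-12
            assert np.array_equal(lags, lags_o)

    def test_lag_axis_in_seconds(self):
        tr = _pulse_trace(20, 10, lag=2)
        tr = RoiTrace(1, tr.t_s * 0.5, tr.intensity_ref, tr.intensity_query, 0.5)
        lags, r = pk.temporal_cross_correlation(tr, max_lag_frames=8)
        assert lags[np.argmax(r)] == pytest.approx(1.0)  # 2 frames × 0.5 s

    def test_zero_variance_channel_rejected(self):
        tr = RoiTrace(1, np.arange(40.0), np.ones(40), np.random.rand(40), 1.0)
        with pytest.raises(ValueError):
            pk.temporal_cross_correlation(tr, max_lag_frames=5)

    def test_short_trace_rejected(self):
        tr = _pulse_trace(2, 2, n=10)
        with pytest.raises(ValueError):
            pk.temporal_cross_correlation(tr, max_lag_frames=10)


class TestAggregateLagProfiles:
    def test_identical_profiles_have_zero_sem(self):
        lags = np.arange(-3.0, 4.0)
        r = np.exp(-(lags**2))
        prof = pk.aggregate_lag_profiles([(lags, r)] * 5)
        assert np.allclose(prof.mean_r, r)
        assert np.allclose(prof.sem_r, 0.0)
        assert prof.n_rois == 5
        assert prof.peak_lag_s == 0.0

    def test_peak_tie_broken_toward_zero_then_positive(self):
        lags = np.arange(-2.0, 3.0)
        r = np.array([0.5, 0.9, 0.2, 0.9, 0.5])
        assert pk.aggregate_lag_profiles([(lags, r)]).peak_lag_s == 1.0
        r2 = np.array([0.9, 0.1, 0.9, 0.1, 0.9])
        assert pk.aggregate_lag_profiles([(lags, r2)]).peak_lag_s == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pk.aggregate_lag_profiles([])

    def test_channel_swap_negates_peak_lag(self):
        tr = _pulse_trace(20, 10, lag=2)
        swapped = RoiTrace(1, tr.t_s, tr.intensity_query, tr.intensity_ref, 1.0)
        p1 = pk.aggregate_lag_profiles([pk.temporal_cross_correlation(tr, 8)])
        p2 = pk.aggregate_lag_profiles([pk.temporal_cross_correlation(swapped, 8)])
        assert p1.peak_lag_s == -p2.peak_lag_s != 0


class TestEndToEndLagRecovery:
    def test_programmed_one_second_delay_recovered(self):
        """Reference channel leading by 1 s yields an aggregated peak at +1 s."""
        p = pk.SimulationParams(seed=17, n_frames=120, field_height_px=160,
                                field_width_px=160, coloc_fraction=1.0, lag_s=1.0)
        ma, mb, _ = pk.simulate_two_channel_movie(p)
        det_a = pk.detect_stack(ma)
        det_b = pk.detect_stack(mb)
        prof, _, _ = pk.roi_lag_analysis(det_a.masks, det_b.masks, ma, mb)
        assert prof.n_rois >= 50
        assert prof.peak_lag_s == 1.0


class TestDensity:
    def test_hand_computed_density(self):
        masks = np.zeros((1, 40, 40), bool)
        import pandas as pd
        puncta = pd.DataFrame(
            {"frame": [0] * 5, "label_id": range(1, 6),
             "x_px": [5, 10, 15, 20, 25], "y_px": [5] * 5, "area_px": [4] * 5}
        )
        det = pk.DetectionResult(masks=masks, puncta=puncta, pixel_size_um=0.2)
        cell = np.zeros((40, 40), bool)
        cell.ravel()[:1000] = True  # 1000 px × 0.04 µm² = 40 µm²
        trace = pk.puncta_density_trace(det, cell, 0.2)
        assert trace.cell_area_um2 == pytest.approx(40.0)
        assert trace.dots_per_um2[0] == pytest.approx(0.125)

    def test_no_puncta_gives_zero_density(self):
        import pandas as pd
        det = pk.DetectionResult(
            masks=np.zeros((2, 16, 16), bool),
            puncta=pd.DataFrame(columns=["frame", "label_id", "x_px", "y_px", "area_px"]),
            pixel_size_um=0.13,
        )
        trace = pk.puncta_density_trace(det, np.ones((16, 16), bool), 0.13)
        assert np.all(trace.dots_per_um2 == 0.0)

    def test_empty_cell_mask_rejected(self):
        import pandas as pd
        det = pk.DetectionResult(
            masks=np.zeros((1, 16, 16), bool),
            puncta=pd.DataFrame(columns=["frame", "label_id", "x_px", "y_px", "area_px"]),
            pixel_size_um=0.13,
        )
        with pytest.raises(ValueError):
            pk.puncta_density_trace(det, np.zeros((16, 16), bool), 0.13)

    def test_recovered_density_tracks_ground_truth(self, small_movie_pair,
                                                   small_detections,
                                                   default_small_params):
        _, _, gt = small_movie_pair
        det_a, _ = small_detections
        p = default_small_params
        cell = np.ones((p.field_height_px, p.field_width_px), bool)
        trace = pk.puncta_density_trace(det_a, cell, p.pixel_size_um,
                                        p.frame_interval_s)
        true_density = gt.density_trace(p).mean()
        assert trace.dots_per_um2.mean() == pytest.approx(true_density, rel=0.10)


class TestPrePost:
    def _trace(self, values, dt=1.0):
        v = np.asarray(values, float)
        return pk.DensityTrace(np.arange(len(v)) * dt, v, cell_area_um2=100.0)

    def test_constant_trace_equal_means(self):
        tr = self._trace(np.full(120, 0.05))
        pre, post = pk.pre_post_summary(tr, t_event_s=30.0)
        assert pre == pytest.approx(0.05)
        assert post == pytest.approx(pre)

    def test_step_doubling_recovered_exactly(self):
        v = np.where(np.arange(121) > 30, 0.08, 0.04)
        tr = self._trace(v)
        pre, post = pk.pre_post_summary(tr, t_event_s=30.0)
        assert post / pre == pytest.approx(2.0)

    def test_window_outside_trace_rejected(self):
        tr = self._trace(np.full(50, 1.0))
        with pytest.raises(ValueError):
            pk.pre_post_summary(tr, t_event_s=30.0, post_window_s=90.0)


class TestShockCurves:
    def _trace(self, values):
        v = np.asarray(values, float)
        return pk.DensityTrace(np.arange(len(v), dtype=float), v, 100.0)

    def test_constant_cells_normalize_to_one(self):
        cells = [self._trace(np.full(60, c)) for c in (0.02, 0.05, 0.4)]
        curves, median, t = pk.shock_response_curves(cells, t_shock_s=30.0)
        for c in curves:
            assert np.allclose(c, 1.0)
        assert np.allclose(median, 1.0)
        assert t[30] == 0.0  # axis shifted so shock sits at 0

    def test_step_cell_median_tracks_step(self):
        v = np.where(np.arange(60) >= 30, 0.3, 0.1)
        curves, median, t = pk.shock_response_curves([self._trace(v)], 30.0)
        assert np.allclose(median[t < 0], 1.0)
        assert np.allclose(median[t >= 0], 3.0)

    def test_zero_baseline_cells_excluded(self):
        good = self._trace(np.full(60, 0.1))
        bad = self._trace(np.zeros(60))
        curves, median, _ = pk.shock_response_curves([good, bad], 30.0)
        assert len(curves) == 1

    def test_all_zero_baselines_rejected(self):
        with pytest.raises(ValueError):
            pk.shock_response_curves([self._trace(np.zeros(60))], 30.0)

    def test_onset_offset_shifts_half_rise(self):
        base = np.where(np.arange(80) >= 40, 2.0, 1.0)
        delayed = np.where(np.arange(80) >= 41, 2.0, 1.0)
        _, m1, t = pk.shock_response_curves([self._trace(base)] * 3, 40.0)
        _, m2, _ = pk.shock_response_curves([self._trace(delayed)] * 3, 40.0)
        half = 1.5
        rise1 = t[np.argmax(m1 >= half)]
        rise2 = t[np.argmax(m2 >= half)]
        assert rise2 - rise1 == pytest.approx(1.0)
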