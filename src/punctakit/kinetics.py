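"""Temporal analyses: ROI traces, signed-lag cross-correlation, densities.

The temporal pipeline mirrors the dual-channel recruitment analysis used for
endocytic proteins: binarized wavelet masks of both channels are projected
over time, their AND defines "island-like" ROIs where both proteins appear;
mean raw intensities over each ROI give per-channel recruitment traces; and
the normalized cross-correlation of those traces as a function of signed lag
times the recruitment order.  The sign convention follows the dynamin-as-
reference analysis: a peak at **positive** lag means the reference channel's
signal precedes the query channel's (reference recruited first).

Puncta densities (dots/µm² of cell footprint) and pre/post perturbation
summaries quantify puncta accumulation under drugs or hyperosmotic shock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .movie import Movie
from .wavelet import DetectionResult

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class ROISet:
    """Disjoint 8-connected ROIs of the dual-channel occupancy mask.

    ``label_map`` is H×W with 0 = background and ids 1..n in raster order
    (order of first pixel in row-major scan).
    """

    label_map: np.ndarray
    areas_px: dict[int, int]

    @property
    def n_rois(self) -> int:
        return len(self.areas_px)

    def pixels(self, roi_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.label_map == roi_id)


@dataclass
class RoiTrace:
    """Per-ROI mean-intensity time courses for reference and query channels."""

    roi_id: int
    t_s: np.ndarray
    intensity_ref: np.ndarray
    intensity_query: np.ndarray
    frame_interval_s: float


@dataclass
class LagCorrelationProfile:
    """Across-ROI mean ± s.e.m. cross-correlation per signed lag (seconds)."""

    lags_s: np.ndarray
    mean_r: np.ndarray
    sem_r: np.ndarray
    n_rois: int

    @property
    def peak_lag_s(self) -> float:
        """Lag of maximal mean r; ties broken toward 0, then toward positive."""
        rmax = self.mean_r.max()
        cands = self.lags_s[np.isclose(self.mean_r, rmax)]
        return float(min(cands, key=lambda lag: (abs(lag), -np.sign(lag))))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "mean_r": self.mean_r, "sem_r": self.sem_r,
             "n_rois": self.n_rois}
        )


@dataclass
class DensityTrace:
    """Puncta density (dots/µm² of cell footprint) per frame."""

    t_s: np.ndarray
    dots_per_um2: np.ndarray
    cell_area_um2: float
    pre_mean: Optional[float] = None
    post_mean: Optional[float] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "dots_per_um2": self.dots_per_um2})


def build_rois(
    masks_a: np.ndarray, masks_b: np.ndarray, min_area_px: int = 4
) -> ROISet:
    """Index ROIs where both channels are significant at some time.

    Each channel's mask stack is projected over time (a pixel is occupied if
    ever significant in that channel); the AND of the two occupancy images is
    then split into 8-connected components of area ≥ ``min_area_px``.
    Symmetric in the channel arguments.
    """
    a = np.asarray(masks_a, dtype=bool)
    b = np.asarray(masks_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask stacks differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise ValueError(f"mask stacks must be T×H×W, got {a.ndim}-D")
    dual = a.any(axis=0) & b.any(axis=0)
    labels, n = ndimage.label(dual, structure=_CONN8)
    label_map = np.zeros_like(labels)
    areas: dict[int, int] = {}
    next_id = 0
    # relabel in raster order of first pixel, dropping small components
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        flat = labels.ravel()
        labs, first = np.unique(flat, return_index=True)
        first_idx = dict(zip(labs.tolist(), first.tolist()))
        kept = [lab for lab in range(1, n + 1) if sizes[lab - 1] >= min_area_px]
        kept.sort(key=lambda lab: first_idx[lab])
        for lab in kept:
            next_id += 1
            comp = labels == lab
            label_map[comp] = next_id
            areas[next_id] = int(sizes[lab - 1])
    return ROISet(label_map=label_map, areas_px=areas)


def extract_traces(
    roiset: ROISet, movie_ref: Movie, movie_query: Movie
) -> list[RoiTrace]:
    """Mean raw intensity over each ROI per frame, for both channels.

    Intensities come from the *original* (unfiltered) stacks; the wavelet
    masks only define where to measure.
    """
    if not movie_ref.same_calibration(movie_query):
        raise ValueError("reference and query movies differ in shape or calibration")
    if roiset.label_map.shape != movie_ref.frames.shape[1:]:
        raise ValueError("ROI label map does not match the movies' frame shape")
    traces = []
    t_s = movie_ref.times_s
    for roi_id in sorted(roiset.areas_px):
        ys, xs = roiset.pixels(roi_id)
        ref = movie_ref.frames[:, ys, xs].mean(axis=1)
        query = movie_query.frames[:, ys, xs].mean(axis=1)
        traces.append(
            RoiTrace(roi_id, t_s, ref.astype(float), query.astype(float),
                     movie_ref.frame_interval_s)
        )
    return traces


def temporal_cross_correlation(
    trace: RoiTrace, max_lag_frames: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of one ROI's two traces vs signed lag.

    Both series are mean-subtracted and scaled to unit variance over their
    full length; ``r(τ) = (1/N_τ) Σ_t ref(t)·query(t+τ)`` over the valid
    overlap, for integer τ in ``[-max_lag, +max_lag]``.  Positive τ means the
    reference leads.  Returns ``(lags_s, r)``.

    Raises ``ValueError`` for traces too short or with a zero-variance
    channel (callers exclude such ROIs).
    """
    ref = np.asarray(trace.intensity_ref, dtype=float)
    query = np.asarray(trace.intensity_query, dtype=float)
    n = len(ref)
    if n != len(query):
        raise ValueError("trace channels differ in length")
    if n < 2 * max_lag_frames + 2:
        raise ValueError(
            f"trace length {n} too short for max_lag_frames={max_lag_frames}"
        )
    sd_ref = ref.std()
    sd_query = query.std()
    if sd_ref == 0 or sd_query == 0:
        raise ValueError("zero-variance channel in trace")
    zr = (ref - ref.mean()) / sd_ref
    zq = (query - query.mean()) / sd_query
    lags = np.arange(-max_lag_frames, max_lag_frames + 1)
    r = np.empty(len(lags))
    for i, tau in enumerate(lags):
        if tau >= 0:
            prod = zr[: n - tau] * zq[tau:]
        else:
            prod = zr[-tau:] * zq[: n + tau]
        r[i] = prod.mean()
    return lags * trace.frame_interval_s, r


def aggregate_lag_profiles(
    profiles: Sequence[tuple[np.ndarray, np.ndarray]]
) -> LagCorrelationProfile:
    """Mean ± s.e.m. of per-ROI correlation profiles sharing one lag axis."""
    if len(profiles) == 0:
        raise ValueError("need at least one per-ROI profile")
    lags0 = np.asarray(profiles[0][0], dtype=float)
    rs = np.empty((len(profiles), len(lags0)))
    for i, (lags, r) in enumerate(profiles):
        if not np.allclose(lags, lags0):
            raise ValueError("profiles are not on a common lag axis")
        rs[i] = r
    mean_r = rs.mean(axis=0)
    sem_r = (
        rs.std(axis=0, ddof=1) / np.sqrt(len(profiles))
        if len(profiles) > 1
        else np.zeros_like(mean_r)
    )
    return LagCorrelationProfile(lags0, mean_r, sem_r, n_rois=len(profiles))


def roi_lag_analysis(
    masks_ref: np.ndarray,
    masks_query: np.ndarray,
    movie_ref: Movie,
    movie_query: Movie,
    max_lag_frames: int = 10,
    min_area_px: int = 4,
) -> tuple[LagCorrelationProfile, ROISet, list[RoiTrace]]:
    """Convenience composition: ROIs → traces → per-ROI CCF → aggregate.

    ROIs whose trace has zero variance in either channel are excluded.
    """
    roiset = build_rois(masks_ref, masks_query, min_area_px=min_area_px)
    traces = extract_traces(roiset, movie_ref, movie_query)
    profiles = []
    for tr in traces:
        try:
            profiles.append(temporal_cross_correlation(tr, max_lag_frames))
        except ValueError:
            continue
    if not profiles:
        raise ValueError("no ROI yielded a valid correlation profile")
    return aggregate_lag_profiles(profiles), roiset, traces


def auto_cell_mask(movie: Movie, closing_radius_px: int = 5) -> np.ndarray:
    """Default cell-footprint mask: Otsu threshold of the temporal mean image,
    morphologically closed."""
    mean_img = movie.frames.mean(axis=0)
    thr = threshold_otsu(mean_img)
    mask = mean_img > thr
    if closing_radius_px > 0:
        r = closing_radius_px
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        selem = (yy**2 + xx**2) <= r**2
        mask = ndimage.binary_closing(mask, structure=selem)
    return mask


def puncta_density_trace(
    det: DetectionResult, cell_mask: np.ndarray, pixel_size_um: float,
    frame_interval_s: float = 1.0,
) -> DensityTrace:
    """Puncta per µm² of cell footprint, per frame.

    Counts puncta whose (rounded) centroid pixel lies inside ``cell_mask``;
    the footprint area is ``|mask| · pixel_size_um²``.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    if cell_mask.shape != det.masks.shape[1:]:
        raise ValueError("cell mask shape does not match detection masks")
    area_um2 = float(cell_mask.sum()) * pixel_size_um**2
    n_frames = det.masks.shape[0]
    counts = np.zeros(n_frames)
    h, w = cell_mask.shape
    for _, row in det.puncta.iterrows():
        x = int(round(row["x_px"]))
        y = int(round(row["y_px"]))
        if 0 <= y < h and 0 <= x < w and cell_mask[y, x]:
            counts[int(row["frame"])] += 1
    t_s = np.arange(n_frames) * frame_interval_s
    return DensityTrace(t_s, counts / area_um2, area_um2)


def pre_post_summary(
    trace: DensityTrace,
    t_event_s: float,
    pre_window_s: float = 30.0,
    post_window_s: float = 90.0,
) -> tuple[float, float]:
    """Mean density over the pre and post windows around a perturbation.

    Pre window is ``[t_event − pre_window, t_event)``, post is
    ``(t_event, t_event + post_window]`` — defaults follow the 30 s-pre /
    90 s-post hyperosmotic-shock acquisition protocol.
    """
    t = trace.t_s
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    # the post window may end up to one frame past the last sample (a trace of
    # n frames covers n·dt of acquisition but samples at (n-1)·dt)
    if t_event_s - pre_window_s < t[0] - 1e-9 or t_event_s + post_window_s > t[-1] + dt + 1e-9:
        raise ValueError("pre/post windows extend outside the trace")
    pre_sel = (t >= t_event_s - pre_window_s) & (t < t_event_s)
    post_sel = (t > t_event_s) & (t <= t_event_s + post_window_s)
    if not pre_sel.any() or not post_sel.any():
        raise ValueError("a window contains no samples")
    pre_mean = float(trace.dots_per_um2[pre_sel].mean())
    post_mean = float(trace.dots_per_um2[post_sel].mean())
    trace.pre_mean, trace.post_mean = pre_mean, post_mean
    return pre_mean, post_mean


def shock_response_curves(
    per_cell_traces: Sequence[DensityTrace],
    t_shock_s: float,
    baseline_window_s: float = 30.0,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Baseline-normalized per-cell curves and their point-wise median.

    Each cell's trace is divided by its mean over
    ``[t_shock − baseline_window, t_shock)``; cells with zero baseline are
    excluded.  The time axis is shifted so the shock sits at 0.  Returns
    ``(per-cell normalized curves, median curve, shifted time axis)``.
    """
    if len(per_cell_traces) == 0:
        raise ValueError("need at least one cell")
    t = per_cell_traces[0].t_s
    curves = []
    for trace in per_cell_traces:
        if not np.allclose(trace.t_s, t):
            raise ValueError("cells are not on a common time axis")
        base_sel = (t >= t_shock_s - baseline_window_s) & (t < t_shock_s)
        if not base_sel.any():
            raise ValueError("baseline window contains no samples")
        baseline = trace.dots_per_um2[base_sel].mean()
        if baseline <= 0:
            continue  # zero-baseline cell: excluded
        curves.append(trace.dots_per_um2 / baseline)
    if not curves:
        raise ValueError("all cells had zero baseline")
    median = np.median(np.stack(curves), axis=0)
    return curves, median, t - t_shock_s
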