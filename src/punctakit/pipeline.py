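"""End-to-end orchestration: simulate/load → detect → coloc → kinetics.

``run_pipeline`` executes the enabled stages in order and writes all outputs
under the run directory:

* ``movie_A.tif`` / ``movie_B.tif`` (+ sidecars) and ``ground_truth.csv``
  when simulating;
* ``masks_A.tif`` / ``masks_B.tif`` and ``puncta_{A,B}.csv`` from detection;
* ``overlap_per_frame.csv`` / aggregate overlap in the manifest;
* ``spatial_ccf.csv`` (shift_px, mean r);
* ``lag_profile.csv`` (lag_s, mean_r, sem_r, n_rois) and per-ROI
  ``roi_traces.csv``;
* ``density_{A,B}.csv`` and optional pre/post shock summary;
* ``manifest.json`` with the config hash, package versions, seed and the
  headline numbers of every stage that ran.

Runs are deterministic given the seed; no timestamps enter any output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import overlap_percentage, spatial_cross_correlation_movies
from .config import RunConfig
from .io import read_movie, write_masks, write_movie
from .kinetics import (
    auto_cell_mask,
    pre_post_summary,
    puncta_density_trace,
    roi_lag_analysis,
)
from .movie import Movie
from .simulate import simulate_two_channel_movie
from .wavelet import detect_stack

log = logging.getLogger("punctakit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # hash identifies the analysis, not the destination
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _acquire(config: RunConfig, out: Path) -> tuple[Movie, Movie]:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        movie_a, movie_b, gt = simulate_two_channel_movie(sim)
        write_movie(movie_a, out / "movie_A.tif")
        write_movie(movie_b, out / "movie_B.tif")
        gt.to_dataframe().to_csv(out / "ground_truth.csv", index=False)
        return movie_a, movie_b
    movie_a = read_movie(config.input_a, config.pixel_size_um, config.frame_interval_s, "A")
    movie_b = read_movie(config.input_b, config.pixel_size_um, config.frame_interval_s, "B")
    if not movie_a.same_calibration(movie_b):
        raise ValueError("channel movies differ in shape or calibration")
    return movie_a, movie_b


def run_pipeline(config: RunConfig) -> Path:
    """Run all enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "punctakit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256_16": _config_hash(config),
        "stages": {},
    }

    def _stage(name: str, fn):
        log.info("stage %s", name)
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = "failed"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = "ok"
        return result

    movie_a, movie_b = _stage("acquire", lambda: _acquire(config, out))

    def _detect():
        det_a = detect_stack(movie_a, config.detection)
        det_b = detect_stack(movie_b, config.detection)
        write_masks(det_a.masks, out / "masks_A.tif")
        write_masks(det_b.masks, out / "masks_B.tif")
        det_a.puncta.to_csv(out / "puncta_A.csv", index=False)
        det_b.puncta.to_csv(out / "puncta_B.csv", index=False)
        return det_a, det_b

    det_a, det_b = _stage("detect", _detect)
    manifest["n_puncta_A"] = int(len(det_a.puncta))
    manifest["n_puncta_B"] = int(len(det_b.puncta))

    if config.switches.overlap:
        def _overlap():
            res = overlap_percentage(det_a.masks, det_b.masks)
            res.per_frame.to_csv(out / "overlap_per_frame.csv", index=False)
            return res

        res = _stage("overlap", _overlap)
        manifest["overlap_percent"] = res.overlap_percent

    if config.switches.spatial_ccf:
        def _sccf():
            prof = spatial_cross_correlation_movies(
                movie_a, movie_b, config.detection, config.max_shift_px
            )
            prof.to_dataframe().to_csv(out / "spatial_ccf.csv", index=False)
            return prof

        prof = _stage("spatial_ccf", _sccf)
        manifest["spatial_ccf_peak_shift_px"] = prof.peak_shift_px
        zero = prof.r[prof.shifts_px == 0][0]
        manifest["spatial_ccf_r_at_0"] = None if np.isnan(zero) else float(zero)

    if config.switches.temporal_ccf:
        def _tccf():
            # clamp the lag window so short movies still yield valid traces
            max_lag = min(config.max_lag_frames, (movie_a.n_frames - 2) // 2)
            if max_lag < config.max_lag_frames:
                log.warning("max_lag_frames clamped to %d for a %d-frame movie",
                            max_lag, movie_a.n_frames)
            lag_prof, roiset, traces = roi_lag_analysis(
                det_a.masks, det_b.masks, movie_a, movie_b,
                max_lag_frames=max_lag,
                min_area_px=config.detection.min_area_px,
            )
            lag_prof.to_dataframe().to_csv(out / "lag_profile.csv", index=False)
            rows = []
            for tr in traces:
                for i, t in enumerate(tr.t_s):
                    rows.append(
                        {"roi_id": tr.roi_id, "t_s": t,
                         "intensity_ref": tr.intensity_ref[i],
                         "intensity_query": tr.intensity_query[i]}
                    )
            pd.DataFrame(rows).to_csv(out / "roi_traces.csv", index=False)
            return lag_prof

        lag_prof = _stage("temporal_ccf", _tccf)
        manifest["peak_lag_s"] = lag_prof.peak_lag_s
        manifest["n_rois"] = lag_prof.n_rois

    if config.switches.density or config.switches.shock:
        def _density():
            traces = {}
            for label, movie, det in (("A", movie_a, det_a), ("B", movie_b, det_b)):
                if config.simulation is not None:
                    # synthetic fields have no cell boundary: footprint = field
                    cell_mask = np.ones(movie.frames.shape[1:], dtype=bool)
                else:
                    cell_mask = auto_cell_mask(movie)
                    if not cell_mask.any():
                        cell_mask = np.ones(movie.frames.shape[1:], dtype=bool)
                trace = puncta_density_trace(
                    det, cell_mask, movie.pixel_size_um, movie.frame_interval_s
                )
                trace.to_dataframe().to_csv(out / f"density_{label}.csv", index=False)
                traces[label] = trace
            return traces

        traces = _stage("density", _density)
        manifest["mean_density_A_per_um2"] = float(np.mean(traces["A"].dots_per_um2))
        manifest["mean_density_B_per_um2"] = float(np.mean(traces["B"].dots_per_um2))

        if config.switches.shock:
            def _shock():
                summary = {}
                for label, trace in traces.items():
                    pre, post = pre_post_summary(
                        trace, config.t_shock_s, config.pre_window_s, config.post_window_s
                    )
                    summary[label] = {"pre_mean": pre, "post_mean": post}
                return summary

            manifest["shock_pre_post"] = _stage("shock", _shock)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return out
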