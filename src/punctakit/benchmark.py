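"""Detection benchmarking against simulated ground truth.

Per frame, detected centroids are matched one-to-one to the positions of
ground-truth events active in that frame by minimum-cost (Hungarian)
assignment, gated at a maximum match radius.  Matches count as true
positives; unmatched detections are false positives, unmatched true events
false negatives.  Recall, precision and centroid RMSE summarize a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .simulate import GroundTruth, SimulationParams
from .wavelet import DetectionResult


@dataclass
class DetectionMetrics:
    recall: float
    precision: float
    centroid_rmse_px: float
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def f1(self) -> float:
        if self.recall + self.precision == 0:
            return 0.0
        return 2 * self.recall * self.precision / (self.recall + self.precision)


def match_points(
    true_xy: np.ndarray, det_xy: np.ndarray, max_dist_px: float
) -> list[tuple[int, int, float]]:
    """One-to-one gated Hungarian matching; returns (true_idx, det_idx, dist)."""
    if len(true_xy) == 0 or len(det_xy) == 0:
        return []
    d = np.linalg.norm(true_xy[:, None, :] - det_xy[None, :, :], axis=-1)
    big = max_dist_px * 1e6 + 1.0
    cost = np.where(d <= max_dist_px, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(rows, cols)
        if d[i, j] <= max_dist_px
    ]


def evaluate_detection(
    det: DetectionResult,
    gt: GroundTruth,
    params: SimulationParams,
    channel: str,
    max_dist_px: float = 2.0,
) -> DetectionMetrics:
    """Frame-by-frame matched recall / precision / centroid RMSE."""
    n_true = n_det = n_match = 0
    sq_err: list[float] = []
    dt = params.frame_interval_s
    for t in range(params.n_frames):
        active = gt.active_events(channel, t * dt)
        true_xy = np.array([[e.x_px, e.y_px] for e in active], dtype=float).reshape(-1, 2)
        frame_det = det.frame_puncta(t)
        det_xy = frame_det[["x_px", "y_px"]].to_numpy(dtype=float).reshape(-1, 2)
        matches = match_points(true_xy, det_xy, max_dist_px)
        n_true += len(true_xy)
        n_det += len(det_xy)
        n_match += len(matches)
        sq_err.extend(dist**2 for _, _, dist in matches)
    recall = n_match / n_true if n_true else 1.0
    precision = n_match / n_det if n_det else 1.0
    rmse = float(np.sqrt(np.mean(sq_err))) if sq_err else 0.0
    return DetectionMetrics(recall, precision, rmse, n_true, n_det, n_match)
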