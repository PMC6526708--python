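"""Dual-channel colocalization scoring.

Two complementary readouts of spatial coincidence between detected channels:

* **Overlap percentage** — the pixel-logic score built from the binarized
  wavelet masks: the AND of the two masks is the "overlap" image, their OR the
  "sum" image, and the score is ``100 · |AND| / |OR|`` (a Jaccard index on the
  mask pixels, in percent).  An object-based variant (fraction of
  reference-channel puncta touching the other channel's mask) is provided as a
  secondary, directional metric.

* **Spatial cross-correlation** — Pearson correlation of the two
  wavelet-denoised channels as a function of an integer lateral pixel shift;
  coincident structures give a profile peaked at shift 0 that decays over the
  spot radius, while unrelated channels stay flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import Movie
from .wavelet import DetectionParams, denoise_frame

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class OverlapResult:
    """Pixel-overlap score of two binary masks (or mask stacks).

    ``overlap_percent = 100 · area_and / area_or`` (0 when both masks are
    empty).  For stacks, the headline value is the mean of per-frame scores
    over frames with a nonempty OR image.
    """

    overlap_percent: float
    area_and_px: int
    area_or_px: int
    per_frame: Optional[pd.DataFrame] = None  # frame, overlap_percent, area_and_px, area_or_px


@dataclass
class OverlapAggregate:
    """Across-cell summary in the field's ``mean ± s.d., n`` convention."""

    mean_percent: float
    sd_percent: float
    n: int
    values: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ShiftCorrelationProfile:
    """Pearson correlation per integer lateral shift, symmetric about 0."""

    shifts_px: np.ndarray
    r: np.ndarray  # NaN where undefined (constant overlap region)
    axis: str = "x"

    @property
    def peak_shift_px(self) -> int:
        """Shift of maximal r; ties broken toward 0, then positive."""
        finite = np.isfinite(self.r)
        if not finite.any():
            raise ValueError("profile has no defined correlation values")
        rmax = np.nanmax(self.r)
        cands = self.shifts_px[finite & np.isclose(self.r, rmax)]
        return int(min(cands, key=lambda d: (abs(d), -np.sign(d))))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"shift_px": self.shifts_px, "r": self.r})


def _overlap_counts(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[int, int]:
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return int((a & b).sum()), int((a | b).sum())


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapResult:
    """Score two same-shape binary masks (single frame or T×H×W stacks).

    Symmetric in its arguments.  For stacks, per-frame scores are kept in
    ``per_frame`` and the headline percent averages frames whose OR image is
    nonempty (frames where neither channel detected anything carry no
    colocalization information).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.ndim == 2:
        and_px, or_px = _overlap_counts(a, b)
        pct = 100.0 * and_px / or_px if or_px else 0.0
        return OverlapResult(pct, and_px, or_px)
    if a.ndim != 3:
        raise ValueError(f"masks must be 2-D or 3-D, got {a.ndim}-D")
    rows = []
    for t in range(a.shape[0]):
        and_px, or_px = _overlap_counts(a[t], b[t])
        pct = 100.0 * and_px / or_px if or_px else 0.0
        rows.append({"frame": t, "overlap_percent": pct, "area_and_px": and_px, "area_or_px": or_px})
    per_frame = pd.DataFrame(rows)
    informative = per_frame[per_frame["area_or_px"] > 0]
    headline = float(informative["overlap_percent"].mean()) if len(informative) else 0.0
    return OverlapResult(
        headline,
        int(per_frame["area_and_px"].sum()),
        int(per_frame["area_or_px"].sum()),
        per_frame=per_frame,
    )


def object_overlap_fraction(mask_ref: np.ndarray, mask_other: np.ndarray) -> float:
    """Fraction of reference-channel puncta whose component touches the other mask.

    Directional object-based alternative to the pixel score; 2-D masks only.
    """
    ref = np.asarray(mask_ref, dtype=bool)
    other = np.asarray(mask_other, dtype=bool)
    if ref.shape != other.shape:
        raise ValueError(f"mask shapes differ: {ref.shape} vs {other.shape}")
    labels, n = ndimage.label(ref, structure=_CONN8)
    if n == 0:
        return 0.0
    hits = ndimage.sum_labels(other.astype(float), labels, index=np.arange(1, n + 1))
    return float(np.count_nonzero(hits) / n)


def overlap_across_cells(results: Sequence[OverlapResult | float]) -> OverlapAggregate:
    """Aggregate per-cell overlap percentages as mean ± sample s.d. with n."""
    if len(results) == 0:
        raise ValueError("need at least one per-cell result")
    values = np.array(
        [r.overlap_percent if isinstance(r, OverlapResult) else float(r) for r in results]
    )
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return OverlapAggregate(float(values.mean()), sd, len(values), values)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def spatial_cross_correlation(
    img_a: np.ndarray,
    img_b: np.ndarray,
    max_shift_px: int = 20,
    axis: str = "x",
) -> ShiftCorrelationProfile:
    """Pearson correlation of two images vs integer lateral shift.

    For each shift ``d`` in ``[-max_shift, +max_shift]`` along the chosen axis
    (``"x"`` = columns, ``"y"`` = rows), image B is translated by ``d`` and the
    correlation is computed on the overlapping region only.  A positive peak
    shift means B's structures sit at larger coordinates than A's.  Shifts
    whose overlap region is constant in either image yield NaN.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    ax = 1 if axis == "x" else 0
    if max_shift_px >= a.shape[ax]:
        raise ValueError(
            f"max_shift_px={max_shift_px} must be smaller than the image extent {a.shape[ax]}"
        )
    shifts = np.arange(-max_shift_px, max_shift_px + 1)
    rs = np.empty(len(shifts))
    for i, d in enumerate(shifts):
        # r(d) = corr(A(x), B(x+d)): positive peak ⇔ B's structures sit at larger x
        if d >= 0:
            sl_a = slice(0, a.shape[ax] - d)
            sl_b = slice(d, a.shape[ax])
        else:
            sl_a = slice(-d, a.shape[ax])
            sl_b = slice(0, a.shape[ax] + d)
        if ax == 1:
            ov_a, ov_b = a[:, sl_a], b[:, sl_b]
        else:
            ov_a, ov_b = a[sl_a, :], b[sl_b, :]
        rs[i] = _pearson(ov_a.ravel(), ov_b.ravel())
    return ShiftCorrelationProfile(shifts, rs, axis=axis)


def spatial_cross_correlation_movies(
    movie_a: Movie,
    movie_b: Movie,
    params: DetectionParams | None = None,
    max_shift_px: int = 20,
    axis: str = "x",
) -> ShiftCorrelationProfile:
    """Per-movie spatial CCF on wavelet-denoised frames, averaged over frames.

    Each frame pair is denoised (sum of significant detail planes) and
    correlated per shift; the profile is the mean over frames with defined
    correlations, mirroring one-profile-per-cell reporting.
    """
    params = params or DetectionParams()
    if not movie_a.same_calibration(movie_b):
        raise ValueError("movies differ in shape or calibration")
    acc = np.zeros(2 * max_shift_px + 1)
    counts = np.zeros_like(acc)
    for t in range(movie_a.n_frames):
        da = denoise_frame(movie_a.frames[t], params)
        db = denoise_frame(movie_b.frames[t], params)
        prof = spatial_cross_correlation(da, db, max_shift_px, axis)
        ok = np.isfinite(prof.r)
        acc[ok] += prof.r[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, acc / counts, np.nan)
    shifts = np.arange(-max_shift_px, max_shift_px + 1)
    return ShiftCorrelationProfile(shifts, mean_r, axis=axis)
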