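"""À trous undecimated B3-spline wavelet spot detection.

The à trous ("with holes") scheme smooths a frame with the separable B3-spline
kernel ``[1, 4, 6, 4, 1] / 16``, inserting ``2**(j-1) - 1`` zeros between the
taps at scale ``j``.  The detail plane at scale ``j`` is the difference of
consecutive smooths, ``w_j = c_{j-1} - c_j``, so the planes telescope back to
the input exactly: ``frame = c_J + Σ_j w_j``.  Diffraction-limited puncta
concentrate in the low-order detail planes, while uneven background stays in
the smooth residual — thresholding the detail planes at a robust (MAD-based)
multiple of their noise scale yields a binary "wavelet mask" of significant
spot pixels that all downstream colocalization and kinetics scoring consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import Movie

#: B3-spline scaling kernel (1-D); the 2-D smoothing kernel is its outer product.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: MAD → Gaussian-sigma conversion factor (Φ⁻¹(3/4) ≈ 0.6745).
MAD_TO_SIGMA = 0.6745


def _dilated_kernel(scale: int) -> np.ndarray:
    """1-D B3 kernel with ``2**(scale-1) - 1`` zeros inserted between taps."""
    spacing = 2 ** (scale - 1)
    k = np.zeros(4 * spacing + 1)
    k[::spacing] = B3_KERNEL
    return k


def _smooth(plane: np.ndarray, scale: int) -> np.ndarray:
    """Separable dilated B3 smoothing with mirror-reflected borders."""
    k = _dilated_kernel(scale)
    out = ndimage.convolve1d(plane, k, axis=0, mode="mirror")
    return ndimage.convolve1d(out, k, axis=1, mode="mirror")


@dataclass
class WaveletDecomposition:
    """Per-scale detail planes plus the smooth residual of one frame.

    ``residual + sum(detail_planes)`` reproduces the input to floating-point
    round-off (telescoping identity).
    """

    detail_planes: list[np.ndarray]  # scale j = 1..J
    residual: np.ndarray
    kernel_id: str = "b3spline"

    @property
    def n_scales(self) -> int:
        return len(self.detail_planes)

    def reconstruct(self) -> np.ndarray:
        return self.residual + np.sum(self.detail_planes, axis=0)


@dataclass
class DetectionParams:
    """Thresholding and morphology knobs of the wavelet mask.

    ``detection_scales`` selects which detail planes vote; with
    ``use_multiscale_product`` the support is their AND (equivalently the
    positive multiscale product of the hard-thresholded planes), otherwise
    their OR.  ``k_sigma`` is the threshold in robust noise sigmas per plane.
    """

    n_scales: int = 3
    k_sigma: float = 3.0
    detection_scales: frozenset[int] = frozenset({2, 3})
    min_area_px: int = 4
    use_multiscale_product: bool = True

    def __post_init__(self) -> None:
        self.detection_scales = frozenset(int(s) for s in self.detection_scales)
        if not (1 <= self.n_scales <= 6):
            raise ValueError(f"n_scales must be in 1..6, got {self.n_scales}")
        if not (self.k_sigma > 0):
            raise ValueError(f"k_sigma must be > 0, got {self.k_sigma}")
        if not self.detection_scales <= set(range(1, self.n_scales + 1)):
            raise ValueError(
                f"detection_scales {sorted(self.detection_scales)} not within 1..{self.n_scales}"
            )
        if self.min_area_px < 1:
            raise ValueError(f"min_area_px must be ≥ 1, got {self.min_area_px}")


@dataclass
class DetectionResult:
    """Binary puncta masks plus a labeled puncta table.

    ``puncta`` columns: ``frame`` (0-based index), ``label_id`` (1-based,
    raster order within the frame), ``x_px``/``y_px`` (intensity-weighted
    subpixel centroid, x = column), ``area_px``.
    """

    masks: np.ndarray  # T×H×W bool
    puncta: pd.DataFrame
    pixel_size_um: float

    def frame_puncta(self, frame_index: int) -> pd.DataFrame:
        return self.puncta[self.puncta["frame"] == frame_index]


_PUNCTA_COLUMNS = ["frame", "label_id", "x_px", "y_px", "area_px"]

#: 8-connectivity structuring element for component labeling.
_CONN8 = np.ones((3, 3), dtype=bool)


def atrous_decompose(frame: np.ndarray, n_scales: int) -> WaveletDecomposition:
    """Decompose one frame into ``n_scales`` detail planes + smooth residual."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if n_scales < 1:
        raise ValueError(f"n_scales must be ≥ 1, got {n_scales}")
    if 2**n_scales > min(frame.shape):
        raise ValueError(
            f"n_scales={n_scales} too deep for frame of shape {frame.shape}"
        )
    planes: list[np.ndarray] = []
    current = frame
    for j in range(1, n_scales + 1):
        smoothed = _smooth(current, j)
        planes.append(current - smoothed)
        current = smoothed
    return WaveletDecomposition(planes, current)


def estimate_plane_noise(plane: np.ndarray) -> float:
    """Robust noise scale of a plane: MAD / 0.6745.

    The median absolute deviation is insensitive to the sparse bright spots,
    so the estimate tracks the background-noise level of the detail plane.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("plane is empty")
    med = np.median(plane)
    return float(np.median(np.abs(plane - med)) / MAD_TO_SIGMA)


def significance_support(
    decomp: WaveletDecomposition, params: DetectionParams
) -> np.ndarray:
    """Boolean mask of pixels significant on the selected detail planes.

    A pixel is significant at scale ``j`` when ``w_j > k_sigma · sigma_j``
    with ``sigma_j`` the plane's MAD noise scale; the support is the AND
    across ``detection_scales`` (multiscale product) or their OR.
    """
    if not params.detection_scales:
        raise ValueError("detection_scales is empty")
    per_scale = []
    for j in sorted(params.detection_scales):
        if j > decomp.n_scales:
            raise ValueError(f"scale {j} not present in decomposition (J={decomp.n_scales})")
        w = decomp.detail_planes[j - 1]
        sigma = estimate_plane_noise(w)
        per_scale.append(w > params.k_sigma * sigma)
    support = per_scale[0].copy()
    for m in per_scale[1:]:
        if params.use_multiscale_product:
            support &= m
        else:
            support |= m
    return support


def denoise_frame(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Sum of significant detail-plane coefficients (soft background removal).

    This is the continuous-valued counterpart of the binary support, used as
    the input to spatial cross-correlation where near-binary masks would
    flatten the profile.
    """
    decomp = atrous_decompose(frame, params.n_scales)
    out = np.zeros_like(decomp.residual)
    for j in sorted(params.detection_scales):
        w = decomp.detail_planes[j - 1]
        sigma = estimate_plane_noise(w)
        out += np.where(w > params.k_sigma * sigma, w, 0.0)
    return out


def detect_frame(
    frame: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float,
    frame_index: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect puncta in one frame.

    8-connected components of the significance support with area ≥
    ``min_area_px`` become puncta; centroids are intensity-weighted on the raw
    frame restricted to the component, in 0-based pixel coordinates
    (x = column).  Returns ``(mask, puncta table)``.
    """
    frame = np.asarray(frame, dtype=float)
    decomp = atrous_decompose(frame, params.n_scales)
    support = significance_support(decomp, params)
    labels, n = ndimage.label(support, structure=_CONN8)
    rows: list[dict] = []
    mask = np.zeros_like(support)
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= params.min_area_px) + 1
        label_id = 0
        for lab in keep:
            comp = labels == lab
            mask |= comp
            label_id += 1
            ys, xs = np.nonzero(comp)
            weights = frame[ys, xs]
            total = weights.sum()
            if total > 0:
                cx = float((xs * weights).sum() / total)
                cy = float((ys * weights).sum() / total)
            else:  # degenerate: zero raw intensity over the component
                cx, cy = float(xs.mean()), float(ys.mean())
            rows.append(
                {
                    "frame": frame_index,
                    "label_id": label_id,
                    "x_px": cx,
                    "y_px": cy,
                    "area_px": int(comp.sum()),
                }
            )
    table = pd.DataFrame(rows, columns=_PUNCTA_COLUMNS)
    return mask, table


def detect_stack(movie: Movie, params: DetectionParams | None = None) -> DetectionResult:
    """Apply :func:`detect_frame` independently to every frame of a movie."""
    params = params or DetectionParams()
    masks = np.zeros(movie.shape, dtype=bool)
    tables = []
    for t in range(movie.n_frames):
        mask, table = detect_frame(movie.frames[t], params, movie.pixel_size_um, frame_index=t)
        masks[t] = mask
        tables.append(table)
    tables = [t for t in tables if len(t)]
    puncta = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=_PUNCTA_COLUMNS)
    )
    return DetectionResult(masks=masks, puncta=puncta, pixel_size_um=movie.pixel_size_um)
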