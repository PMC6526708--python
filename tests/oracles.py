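"""Independent brute-force oracles, kept separate from the implementation.

Everything here is written the slow, obvious way (explicit padding, double
loops) so it can serve as ground truth for the fast library code.
"""

import numpy as np

B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def dilated_kernel_2d(scale: int) -> np.ndarray:
    """Full 2-D dilated B3 kernel (outer product of the zero-padded 1-D taps)."""
    spacing = 2 ** (scale - 1)
    k = np.zeros(4 * spacing + 1)
    k[::spacing] = B3
    return np.outer(k, k)


def convolve2d_mirror(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 2-D convolution with mirror (reflect-without-edge) padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="reflect")
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = (padded[i : i + kh, j : j + kw] * kernel).sum()
    return out


def atrous_planes_direct(frame: np.ndarray, n_scales: int):
    """À trous detail planes by explicit dilated-kernel 2-D convolution."""
    planes = []
    current = frame.astype(float)
    for j in range(1, n_scales + 1):
        smoothed = convolve2d_mirror(current, dilated_kernel_2d(j))
        planes.append(current - smoothed)
        current = smoothed
    return planes, current


def scale1_noise_gain() -> float:
    """Std of the scale-1 detail plane of unit white noise: ||δ − h||₂."""
    h = dilated_kernel_2d(1)
    delta = np.zeros_like(h)
    delta[h.shape[0] // 2, h.shape[1] // 2] = 1.0
    return float(np.sqrt(((delta - h) ** 2).sum()))


def pearson_naive(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel().astype(float)
    y = y.ravel().astype(float)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den


def xcorr_naive(ref: np.ndarray, query: np.ndarray, max_lag: int):
    """Double-loop normalized cross-correlation, global z-scoring, 1/N_τ."""
    n = len(ref)
    zr = (ref - ref.mean()) / ref.std()
    zq = (query - query.mean()) / query.std()
    lags = list(range(-max_lag, max_lag + 1))
    rs = []
    for tau in lags:
        acc, cnt = 0.0, 0
        for t in range(n):
            if 0 <= t + tau < n:
                acc += zr[t] * zq[t + tau]
                cnt += 1
        rs.append(acc / cnt)
    return np.array(lags, dtype=float), np.array(rs)
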