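"""Synthetic two-channel spinning-disk movie generator with ground truth.

Emulates single-plane time-lapse movies of diffraction-limited endocytic
puncta: events appear at random positions, stay for a (truncated-normal)
lifetime, and are imaged as isotropic Gaussian spots on a constant background
with Poisson photon noise and Gaussian readout noise.  A configurable fraction
of channel-A events carries a partnered channel-B event at the same position
whose onset is delayed by a programmed lag — the structure the temporal
cross-correlation analysis is meant to recover.

Defaults mimic the imaging regime of EMCCD spinning-disk movies of
clathrin-mediated endocytosis: 0.13 µm/px, 1 s/frame, event lifetimes of
35–50 s, steady-state densities of a few times 0.01 dots/µm², and an
inter-channel lag of ~1 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .movie import Movie

CHANNEL_A = "A"
CHANNEL_B = "B"


@dataclass
class SimulationParams:
    """Parameters of the two-channel puncta simulation.

    ``event_rate`` is the nucleation rate in events·µm⁻²·s⁻¹; the steady-state
    puncta density it implies is ``event_rate * lifetime_mean_s`` dots/µm².
    ``coloc_fraction`` is the fraction of channel-A events with a partnered
    channel-B event at the same position; the partner's onset is shifted by
    ``lag_s`` (positive = B appears after A).  Unpartnered channel-B events are
    added independently so both channels have the same expected density.
    """

    field_height_px: int = 128
    field_width_px: int = 128
    pixel_size_um: float = 0.13
    frame_interval_s: float = 1.0
    n_frames: int = 120
    event_rate: float = 0.0012  # events/µm²/s → ~0.05 dots/µm² at 42 s lifetime
    lifetime_mean_s: float = 42.0
    lifetime_sd_s: float = 5.0
    psf_sigma_px: float = 1.3
    amplitude_photons: float = 200.0
    background_photons: float = 20.0
    readout_noise_sd: float = 2.0
    coloc_fraction: float = 0.5
    lag_s: float = 1.0
    jitter_sd_px: float = 0.0
    burn_in_s: Optional[float] = None  # None → lifetime_mean + 3·sd
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "event_rate",
            "lifetime_mean_s",
            "lifetime_sd_s",
            "psf_sigma_px",
            "amplitude_photons",
            "background_photons",
            "readout_noise_sd",
            "jitter_sd_px",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and ≥ 0, got {v}")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError(f"coloc_fraction must lie in [0, 1], got {self.coloc_fraction}")
        if not math.isfinite(self.lag_s):
            raise ValueError("lag_s must be finite")
        if self.field_height_px < 8 or self.field_width_px < 8:
            raise ValueError("field must be at least 8×8 px")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.burn_in_s is not None and (not math.isfinite(self.burn_in_s) or self.burn_in_s < 0):
            raise ValueError("burn_in_s must be finite and ≥ 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def field_area_um2(self) -> float:
        return self.field_height_px * self.field_width_px * self.pixel_size_um**2

    @property
    def effective_burn_in_s(self) -> float:
        if self.burn_in_s is not None:
            return self.burn_in_s
        return self.lifetime_mean_s + 3.0 * self.lifetime_sd_s


@dataclass
class Event:
    event_id: int
    channel: str
    x_px: float
    y_px: float
    t_on_s: float
    t_off_s: float
    partner_id: Optional[int] = None
    true_lag_s: Optional[float] = None


@dataclass
class GroundTruth:
    """Simulated event list with the colocalization/lag structure made explicit."""

    events: list[Event] = field(default_factory=list)

    def channel_events(self, channel: str) -> list[Event]:
        return [e for e in self.events if e.channel == channel]

    def partnered_pairs(self) -> list[tuple[Event, Event]]:
        """(A event, B partner) tuples; each pair appears once."""
        by_id = {e.event_id: e for e in self.events}
        return [
            (e, by_id[e.partner_id])
            for e in self.events
            if e.channel == CHANNEL_A and e.partner_id is not None
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "channel": e.channel,
                    "x_px": e.x_px,
                    "y_px": e.y_px,
                    "t_on_s": e.t_on_s,
                    "t_off_s": e.t_off_s,
                    "partner_id": e.partner_id,
                    "true_lag_s": e.true_lag_s,
                }
            for e in self.events],
            columns=[
                "event_id", "channel", "x_px", "y_px",
                "t_on_s", "t_off_s", "partner_id", "true_lag_s",
            ],
        )

    def active_events(self, channel: str, t_s: float) -> list[Event]:
        return [e for e in self.channel_events(channel) if e.t_on_s <= t_s < e.t_off_s]

    def density_trace(self, params: SimulationParams, channel: str = CHANNEL_A) -> np.ndarray:
        """True puncta density (dots/µm²) per frame, from the event list."""
        times = np.arange(params.n_frames) * params.frame_interval_s
        counts = np.array([len(self.active_events(channel, t)) for t in times], dtype=float)
        return counts / params.field_area_um2


def _draw_lifetimes(n: int, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal lifetimes with a hard minimum of one frame interval."""
    lo = params.frame_interval_s
    mu, sd = params.lifetime_mean_s, params.lifetime_sd_s
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, max(mu, lo))
    a = (lo - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def sample_events(params: SimulationParams, rng: np.random.Generator) -> GroundTruth:
    """Draw the ground-truth event list for both channels.

    Channel-A onsets form a homogeneous Poisson process on the field over
    ``[-burn_in, duration)`` so the movie starts in steady state; the expected
    number of onsets inside the movie window is
    ``event_rate · area_µm² · duration``.  A Bernoulli(``coloc_fraction``)
    subset of A events gets a channel-B partner at the same position with its
    onset shifted by ``lag_s``; unpartnered B events are added independently at
    rate ``event_rate · (1 − coloc_fraction)`` so both channels match in
    expected density.
    """
    burn_in = params.effective_burn_in_s
    window = params.duration_s + burn_in
    mean_a = params.event_rate * params.field_area_um2 * window

    n_a = rng.poisson(mean_a)
    gt = GroundTruth()
    next_id = 0

    def _new_event(channel: str, x: float, y: float, t_on: float, life: float) -> Event:
        nonlocal next_id
        ev = Event(next_id, channel, x, y, t_on, t_on + life)
        next_id += 1
        gt.events.append(ev)
        return ev

    xs = rng.uniform(0, params.field_width_px, size=n_a)
    ys = rng.uniform(0, params.field_height_px, size=n_a)
    t_ons = rng.uniform(-burn_in, params.duration_s, size=n_a)
    lives_a = _draw_lifetimes(n_a, params, rng)
    partnered = rng.random(n_a) < params.coloc_fraction
    lives_b = _draw_lifetimes(int(partnered.sum()), params, rng)

    j = 0
    for i in range(n_a):
        a = _new_event(CHANNEL_A, xs[i], ys[i], t_ons[i], lives_a[i])
        if partnered[i]:
            bx, by = xs[i], ys[i]
            if params.jitter_sd_px > 0:
                bx = float(np.clip(bx + rng.normal(0, params.jitter_sd_px), 0, params.field_width_px - 1e-9))
                by = float(np.clip(by + rng.normal(0, params.jitter_sd_px), 0, params.field_height_px - 1e-9))
            b = _new_event(CHANNEL_B, bx, by, t_ons[i] + params.lag_s, lives_b[j])
            j += 1
            a.partner_id, b.partner_id = b.event_id, a.event_id
            a.true_lag_s = b.true_lag_s = params.lag_s

    # independent (unpartnered) channel-B events, equalizing expected density
    mean_b = mean_a * (1.0 - params.coloc_fraction)
    n_b = rng.poisson(mean_b) if mean_b > 0 else 0
    xs_b = rng.uniform(0, params.field_width_px, size=n_b)
    ys_b = rng.uniform(0, params.field_height_px, size=n_b)
    t_b = rng.uniform(-burn_in, params.duration_s, size=n_b)
    lives = _draw_lifetimes(n_b, params, rng)
    for i in range(n_b):
        _new_event(CHANNEL_B, xs_b[i], ys_b[i], t_b[i], lives[i])

    return gt


def simulate_shock_movie(
    params: SimulationParams,
    t_shock_s: float,
    rate_factor: float = 2.0,
) -> tuple[Movie, Movie, GroundTruth]:
    """Two-channel movie whose event rate steps by ``rate_factor`` at a shock.

    Mimics a perturbation (drug, hyperosmotic shock) that multiplies the
    nucleation rate at ``t_shock_s``: the baseline process runs at
    ``event_rate`` throughout (with burn-in, so the movie starts in steady
    state) and an extra process at ``(rate_factor - 1) · event_rate`` starts
    at the shock.  Puncta density then relaxes toward ``rate_factor ×``
    baseline with a time constant set by the event lifetime.
    """
    if rate_factor < 1.0:
        raise ValueError(f"rate_factor must be ≥ 1, got {rate_factor}")
    if not (0.0 <= t_shock_s < params.duration_s):
        raise ValueError("t_shock_s must lie inside the movie")
    ss = np.random.SeedSequence(params.seed)
    rng_base, rng_extra, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(4))
    gt = sample_events(params, rng_base)
    if rate_factor > 1.0:
        extra_frames = params.n_frames - int(round(t_shock_s / params.frame_interval_s))
        extra_params = replace(
            params,
            event_rate=params.event_rate * (rate_factor - 1.0),
            n_frames=max(1, extra_frames),
            burn_in_s=0.0,
        )
        extra = sample_events(extra_params, rng_extra)
        offset = len(gt.events)
        for ev in extra.events:
            ev.event_id += offset
            if ev.partner_id is not None:
                ev.partner_id += offset
            ev.t_on_s += t_shock_s
            ev.t_off_s += t_shock_s
            gt.events.append(ev)
    movie_a = render_movie(gt, CHANNEL_A, params, rng_a)
    movie_b = render_movie(gt, CHANNEL_B, params, rng_b)
    return movie_a, movie_b, gt


def _gaussian_patch(
    x: float, y: float, sigma: float, amplitude: float, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Spot footprint sampled at pixel centers, truncated at ±5σ."""
    h, w = shape
    r = int(math.ceil(5.0 * sigma)) + 1
    x0, x1 = max(0, int(math.floor(x)) - r), min(w, int(math.ceil(x)) + r + 1)
    y0, y1 = max(0, int(math.floor(y)) - r), min(h, int(math.ceil(y)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    patch = amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))
    return slice(y0, y1), slice(x0, x1), patch


def render_movie(
    gt: GroundTruth,
    channel: str,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> Movie:
    """Render one channel of the ground truth to a noisy calibrated stack.

    Each event active in a frame (``t_on ≤ t < t_off``) contributes an
    isotropic 2-D Gaussian with sd ``psf_sigma_px`` and peak
    ``amplitude_photons``; a constant background is added, then per-pixel
    Poisson photon noise and additive Gaussian readout noise (gain fixed at
    1 ADU/photon).  Events outside the movie window are clipped, never
    wrapped.  With ``rng=None`` the stack is rendered noise-free.
    """
    events = gt.channel_events(channel)
    if not events and channel not in (CHANNEL_A, CHANNEL_B):
        known = sorted({e.channel for e in gt.events})
        raise KeyError(f"unknown channel {channel!r}; ground truth has {known}")

    h, w = params.field_height_px, params.field_width_px
    stack = np.zeros((params.n_frames, h, w), dtype=float)
    dt = params.frame_interval_s

    for ev in events:
        f0 = max(0, int(math.ceil(ev.t_on_s / dt)))
        f1 = min(params.n_frames, int(math.ceil(ev.t_off_s / dt)))
        if f1 <= f0:
            continue
        ys, xs, patch = _gaussian_patch(
            ev.x_px, ev.y_px, params.psf_sigma_px, params.amplitude_photons, (h, w)
        )
        stack[f0:f1, ys, xs] += patch

    stack += params.background_photons
    if rng is not None:
        stack = rng.poisson(stack).astype(float)
        if params.readout_noise_sd > 0:
            stack += rng.normal(0.0, params.readout_noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)
    return Movie(stack, params.pixel_size_um, params.frame_interval_s, channel=channel)


def simulate_two_channel_movie(
    params: SimulationParams,
) -> tuple[Movie, Movie, GroundTruth]:
    """Sample events and render both channels with independent noise streams.

    All randomness derives from ``params.seed``: one child stream for the
    event list and one per channel for the noise, so identical params give
    byte-identical output.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_events, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))
    gt = sample_events(params, rng_events)
    movie_a = render_movie(gt, CHANNEL_A, params, rng_a)
    movie_b = render_movie(gt, CHANNEL_B, params, rng_b)
    return movie_a, movie_b, gt
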