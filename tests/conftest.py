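"""Shared fixtures: small synthetic movies reused across test modules."""

import numpy as np
import pytest

import punctakit as pk


@pytest.fixture(scope="session")
def default_small_params() -> pk.SimulationParams:
    """Paper-like imaging regime on a small field to keep tests fast."""
    return pk.SimulationParams(
        seed=11, n_frames=40, field_height_px=96, field_width_px=96
    )


@pytest.fixture(scope="session")
def small_movie_pair(default_small_params):
    return pk.simulate_two_channel_movie(default_small_params)


@pytest.fixture(scope="session")
def small_detections(small_movie_pair):
    movie_a, movie_b, _ = small_movie_pair
    params = pk.DetectionParams()
    return pk.detect_stack(movie_a, params), pk.detect_stack(movie_b, params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
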