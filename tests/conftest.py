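import numpy as np
import pytest

from wavetrack import imageproc, simgen
from wavetrack.tracking import SeedAnnotation


@pytest.fixture(scope="session")
def small_movie():
    """A short rendered movie in the default regime, with ground truth."""
    params = simgen.movie_preset(
        "paper-regime-20x", rng_seed=3, duration_min=60.0,
        image_shape=(128, 280), initial_length_um=70.0,
        wave_times_min=[5.0], wave_rate_per_h=1e-9)
    stack, truth = simgen.simulate_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_movie_maps(small_movie):
    _, stack, _ = small_movie
    return [imageproc.make_feature_map(frame) for frame in stack.frames]


@pytest.fixture(scope="session")
def small_movie_seeds(small_movie):
    _, _, truth = small_movie
    return SeedAnnotation(
        soma_point=truth.seeds["soma"], hillock_point=truth.seeds["hillock"],
        edge_point=truth.seeds["edge"], wave_point=truth.seeds["wave"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
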