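import numpy as np
import pytest

from ricestress import SceneConfig, simulate_scene
from ricestress.synthetic_scene import BANDS, ReflectanceStack


@pytest.fixture(scope="session")
def small_scene():
    """A 24x24 default-condition scene shared by read-only tests."""
    config = SceneConfig(n_rows=24, n_cols=24, seed=7)
    stack, labels, dem = simulate_scene(config)
    return config, stack, labels, dem


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, cloud-free scene: the deterministic limit of the generator."""
    config = SceneConfig(n_rows=24, n_cols=24, noise_sd=0.0, cloud_prob=0.0, seed=7)
    stack, labels, dem = simulate_scene(config)
    return config, stack, labels, dem


def random_stack(rng, n_dates=3, n_rows=8, n_cols=8, low=0.02, high=0.9):
    """A positive random reflectance stack with all-valid QA."""
    values = rng.uniform(low, high, size=(n_dates, len(BANDS), n_rows, n_cols))
    qa = np.ones((n_dates, n_rows, n_cols), dtype=bool)
    dates = np.linspace(100, 280, n_dates)
    return ReflectanceStack(values=values, qa=qa, dates=dates)
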