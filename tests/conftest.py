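import numpy as np
import pytest
from hypothesis import settings

from bloomsat import synthetic

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_world():
    """A 10x10 world with one population, no clouds, deterministic."""
    cfg = synthetic.WorldConfig(
        grid_rows=10, grid_cols=10, patch_pixels=16,
        populations=(
            synthetic.PopulationConfig(
                peak_day=60, duration_days=70, amplitude=0.95,
                center_row=4.0, center_col=4.0, spread_cells=4.0),
        ),
        background_fraction=0.35, peak_jitter_days=0.0, seed=42,
    )
    return synthetic.generate_world(cfg)


@pytest.fixture(scope="session")
def three_population_world():
    """Three spatially and phenologically distinct populations."""
    cfg = synthetic.WorldConfig(
        grid_rows=30, grid_cols=30, patch_pixels=8,
        populations=(
            synthetic.PopulationConfig(50, 70, 0.95, 5.0, 5.0, 4.0),
            synthetic.PopulationConfig(170, 70, 0.9, 24.0, 24.0, 4.0),
            synthetic.PopulationConfig(330, 70, 0.9, 5.0, 24.0, 4.0),
        ),
        background_fraction=0.25, peak_jitter_days=3.0, seed=7,
    )
    return synthetic.generate_world(cfg)


@pytest.fixture(scope="session")
def patch_dataset():
    X, y = synthetic.make_patch_dataset(500, side=32, seed=5)
    assert 0 < y.sum() < y.size
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
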