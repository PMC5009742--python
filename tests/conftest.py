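import numpy as np
import pytest

from exparkit import CurveModel, generate_curve


@pytest.fixture
def fine_grid():
    """0.1-minute read grid over a 30-minute run."""
    return np.arange(0.0, 30.0 + 1e-9, 0.1)


@pytest.fixture
def plate_grid():
    """1-minute read grid over a 60-minute run (instrument default)."""
    return np.arange(0.0, 60.0 + 1e-9, 1.0)


@pytest.fixture
def noiseless_curve():
    """Factory for clean sigmoids with a known true POI."""

    def make(poi_true, t_grid, **kwargs):
        model = CurveModel(noise_sd=0.0, drift=0.0, poi_true=poi_true, **kwargs)
        return generate_curve(model, t_grid)

    return make
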