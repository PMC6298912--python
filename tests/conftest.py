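import numpy as np
import pytest
from hypothesis import settings

from ceusquant import BolusModelParams, TimeIntensityCurve, evaluate_model

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# canonical worked example used across the suite: a bolus arriving 2 s
# after the acquisition start with unit-normalised lognormal transit
CANONICAL = BolusModelParams(O=5.0, A=100.0, mu=1.0, sigma=0.5, t0=2.0)


@pytest.fixture
def canonical_params() -> BolusModelParams:
    return CANONICAL


@pytest.fixture
def acquisition_grid() -> np.ndarray:
    """55 s record at 36 frames/s, frame 0 at t = 0."""
    return np.arange(int(55 * 36)) / 36.0


@pytest.fixture
def noiseless_tic(canonical_params, acquisition_grid) -> TimeIntensityCurve:
    y = evaluate_model(canonical_params, acquisition_grid)
    return TimeIntensityCurve(times=acquisition_grid, intensities=y)
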