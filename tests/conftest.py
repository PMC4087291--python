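import numpy as np
import pytest

from isodose import (
    BeamGeometry,
    BeamModelParams,
    GridSpec,
    sample_curves_from_truth,
    separable_truth,
    synth_pdd,
    synth_profile,
)


@pytest.fixture(scope="session")
def geom():
    return BeamGeometry(ssd=100.0, field_size=10.0, phantom_halfwidth=25.0, phantom_depth=30.0)


@pytest.fixture(scope="session")
def params():
    return BeamModelParams()


@pytest.fixture(scope="session")
def fine_grid():
    """0.1 cm pixel grid spanning the scoring footprint, axis column included."""
    return GridSpec.from_extents(0.1, 15.0, 27.95)


@pytest.fixture(scope="session")
def coarse_grid():
    """Small, quick 0.5 cm grid for oracle comparisons."""
    return GridSpec.from_extents(0.5, 12.5, 25.0)


@pytest.fixture(scope="session")
def default_curves(params, geom):
    """Analytic PDD/profile pair sampled densely."""
    pdd = synth_pdd(params, np.arange(0.0, 28.01, 0.05))
    prof = synth_profile(params, geom, np.arange(-15.0, 15.01, 0.1))
    return pdd, prof


@pytest.fixture(scope="session")
def separable_closure(params, geom, fine_grid):
    """Truth plane plus the curves sampled from it (the closure inputs)."""
    truth = separable_truth(params, geom, fine_grid)
    pdd, prof = sample_curves_from_truth(truth)
    return truth, pdd, prof
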