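import numpy as np
import pytest

from critb import GridSpec, PointSet, Raster
from critb.landscape import TruthParams, generate_bundle


@pytest.fixture
def spec10():
    return GridSpec(10, 10, 1.0)


@pytest.fixture(scope="session")
def small_bundle():
    """A 60x60 synthetic study system with the default specialist truth."""
    return generate_bundle(
        spec=GridSpec(60, 60, 1.0), n_env_layers=6, n_occurrences=150, seed=101
    )


@pytest.fixture
def uniform_points():
    rng = np.random.default_rng(7)
    return PointSet(rng.uniform(0, 10, size=(40, 2)))


def make_mask_raster(spec, fill=0.5):
    return Raster(spec, np.full(spec.shape, fill))
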