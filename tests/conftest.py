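import numpy as np
import pytest

from slicealign import SimulationSpec, Slice, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_slice(rng):
    """20 labeled spots with distinct expression profiles."""
    coords = rng.uniform(0, 50, size=(20, 2))
    features = rng.poisson(5.0, size=(20, 12)).astype(float) + np.eye(20, 12) * 40
    return Slice(
        coords=coords,
        features=features,
        feature_names=[f"g{i}" for i in range(12)],
        cell_types=[f"t{i % 3}" for i in range(20)],
        slice_id="small",
    )


@pytest.fixture
def clean_pair():
    """Full-overlap pair, 60 deg rotation, identical expression on both sides."""
    spec = SimulationSpec(
        n_spots=120,
        n_genes=40,
        rotation_deg=60.0,
        translation=(5.0, -3.0),
        expression_model="poisson",
        resample_expression=False,
        seed=7,
    )
    return make_pair(spec)
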