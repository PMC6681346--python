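import numpy as np
import pytest

from phenotax.registry_io import COMPOUNDS, Dataset, SampleProfile


def make_profile(values, species="Erica", sample_id="s1", recovery=None):
    """Build a SampleProfile from a 16-vector of contents."""
    values = np.asarray(values, dtype=float)
    assert values.shape == (16,)
    return SampleProfile(
        sample_id=sample_id,
        species=species,
        contents=dict(zip(COMPOUNDS, values.tolist())),
        recovery=recovery,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_dataset(rng):
    """Ten random strictly-positive profiles with recovery fractions."""
    samples = []
    for i in range(10):
        values = rng.uniform(0.05, 5.0, size=16)
        recovery = float(rng.uniform(0.5, 1.0))
        samples.append(
            make_profile(values, species="unknown", sample_id=f"r{i}", recovery=recovery)
        )
    return Dataset(samples)
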