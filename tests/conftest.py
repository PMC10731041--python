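import numpy as np
import pytest

from dfncstates import ComponentTimeSeries, default_templates


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def noise_series(rng):
    """White-noise 8-component series at the reference TR."""
    return ComponentTimeSeries("sub-noise", rng.standard_normal((230, 8)), 2.5)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def template_z(templates):
    """Planted templates as Fisher-z matrices with zero diagonal."""
    z = np.arctanh(np.clip(np.stack([t.correlation for t in templates]), -0.999999, 0.999999))
    for i in range(z.shape[0]):
        np.fill_diagonal(z[i], 0.0)
    return z
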