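import numpy as np
import pytest

from ecmlines import pattern_design as pat


@pytest.fixture(scope="session")
def small_field():
    """A modest random field reused by read-only tests."""
    return pat.generate_field(
        density=60, dispersion_deg=30.0, line_width_um=1.0,
        field_size=(120.0, 120.0), seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
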