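import math

import pytest

from rdsphere import ModelParameters

PI = math.pi


@pytest.fixture
def params_factory():
    """Factory for dimensionless parameter bundles: phi in units of pi."""

    def make(phi_over_pi: float, c_t0=1.0, c_r1: float = 0.0, alpha: float = 1.0):
        return ModelParameters.from_dimensionless(
            phi=phi_over_pi * PI, alpha=alpha, c_t0=c_t0, c_r1=c_r1
        )

    return make
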