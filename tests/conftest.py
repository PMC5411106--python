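import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from homeoflux import ParameterSet, build_model

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def draw_params(rng: np.random.Generator, kgTc_zero: bool = False) -> ParameterSet:
    """Random valid rate constants, log-uniform in [0.1, 10], 3 sig. digits.

    Rounding keeps the exact-rational symbolic checks fast.
    """
    def r():
        return float(np.format_float_positional(
            10.0 ** rng.uniform(-1, 1), precision=3, fractional=False))

    return ParameterSet(
        kcat=r(), Kext=r(), kgS=r(), aT=r(),
        kgTc=0.0 if kgTc_zero else r(), kgTa=r(),
        Ksyn=r(), Kdeg=r(), n=float(rng.integers(1, 5)),
        Ksensor=r(), ksens=r())


@pytest.fixture
def unit_params():
    return ParameterSet()


@pytest.fixture
def perfect_model():
    """Activity-dependent downregulation without basal degradation:
    the canonical globally perfect architecture."""
    return build_model("activity_dependent", ParameterSet(kgTc=0.0, kgTa=1.0))


@pytest.fixture
def grid41():
    return np.geomspace(1e-2, 1e2, 41)
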