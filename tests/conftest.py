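import pytest

from kinesin14 import NeckElasticity, PotentialGeometry, ThermoContext


@pytest.fixture
def thermo():
    """Room-temperature thermal context with the default splitting factor."""
    return ThermoContext(kBT=4.114, lam=0.5)


@pytest.fixture
def geom4():
    """Standard working geometry: 8 nm lattice, asymmetry alpha = 4."""
    return PotentialGeometry(d=8.0, alpha=4.0)


@pytest.fixture
def gikin_elasticity():
    """GiKIN14a-family defaults apart from kappa (set per test)."""
    def make(kappa):
        return NeckElasticity(kappa=kappa, Delta=0.5, DeltaD=3.5, dE_neck_T=0.8)
    return make
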