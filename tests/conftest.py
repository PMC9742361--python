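import numpy as np
import pytest

from flashox import (BoundarySupply, Geometry1D, GridSpec, TissueParameters,
                     equilibrate, make_domain_1d)


@pytest.fixture(scope="session")
def tissue():
    return TissueParameters()


@pytest.fixture(scope="session")
def fast_grid():
    """Coarse, short-stage grid for tests that only need plumbing."""
    return GridSpec(dx=2.5, steps_per_stage=100)


def domain_1d(spacing, supply, dx=0.5):
    geom = Geometry1D(spacing, BoundarySupply(supply), BoundarySupply(supply))
    return make_domain_1d(geom, dx)


@pytest.fixture(scope="session")
def eq_50_10(tissue):
    """Equilibrium between vessels 50 μm apart supplying 10.1 μM."""
    domain = domain_1d(50, 10.1)
    return domain, equilibrate(domain, tissue, GridSpec())
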