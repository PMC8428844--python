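import numpy as np
import pytest

import crevo


@pytest.fixture
def spec09():
    return crevo.TradeoffSpec(gamma=0.9)


@pytest.fixture
def spec1():
    return crevo.TradeoffSpec(gamma=1.0)


@pytest.fixture
def chemostat_env():
    """Symmetric 3-resource chemostat: s=1, K=1, mu=0.1, delta=0.25."""
    return crevo.EnvironmentSpec.symmetric()


@pytest.fixture
def mu0_env():
    """Same chemostat without resource decay (closed-form regime)."""
    return crevo.EnvironmentSpec.symmetric(decay=0.0)


@pytest.fixture
def batch_env():
    """Environment for serial-dilution batches (only K and q are used)."""
    return crevo.EnvironmentSpec(
        supply=[0.0, 0.0, 0.0], monod_K=1.0, decay=0.0, death_rate=0.0
    )


@pytest.fixture
def protocol():
    """Standard dilution protocol: rho0=1e-3, c(0)=K, c_fin=1e-8."""
    return crevo.DilutionProtocol(
        rho0=1e-3, c_init=[1.0, 1.0, 1.0], c_fin=1e-8, n_batches=1
    )


@pytest.fixture
def ctrl():
    return crevo.IntegrationControl(extinction_threshold=1e-12)


def community(phenotypes, densities, concentrations, time=0.0):
    return crevo.CommunityState(
        strains=list(zip(phenotypes, densities)),
        concentrations=np.asarray(concentrations, dtype=float),
        time=time,
    )
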