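import numpy as np
import pytest

import mscortex as mc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_connectome():
    """z=4 regions of m=20 neurons at (rho=0.9, sigma=0.5); reused read-only."""
    return mc.build_connectome(
        4, 20, mc.SmallWorldParams(), mc.InterRegionParams(0.9, 0.5), seed=7
    )


@pytest.fixture(scope="session")
def default_structural_sweep():
    """The reference structural sweep: default grids, z=9, m=100, 10 replicates."""
    from mscortex.sweep import SweepConfig, run_structural_sweep

    return run_structural_sweep(SweepConfig(base_seed=1))


@pytest.fixture(scope="session")
def default_connectome():
    """One realization at the reference configuration z=9, m=100."""
    return mc.build_connectome(
        9, 100, mc.SmallWorldParams(), mc.InterRegionParams(0.9, 0.5), seed=42
    )
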