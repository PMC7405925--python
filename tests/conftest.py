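import numpy as np
import pytest

import ffnprop as fp


@pytest.fixture(scope="session")
def lif():
    return fp.LIFParams()


@pytest.fixture(scope="session")
def kernel(lif):
    return fp.build_synapse_kernel(dt=lif.dt)


@pytest.fixture(scope="session")
def layer1_run(lif, kernel):
    """A modest standard first-layer run shared across tests.

    N = 100 neurons, 20 s, noise std 30, slow OU stimulus.
    """
    duration = 20_000.0
    stim = fp.generate_ou(
        fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), duration, seed=101
    )
    config = fp.NetworkConfig(n_layers=1, n_per_layer=100, noise_std=30.0)
    raster = fp.simulate_ffn(config, stim, lif, kernel, master_seed=202)
    return stim, raster
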