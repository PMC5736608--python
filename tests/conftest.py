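import numpy as np
import pytest

from thetagamma import SyntheticConfig, gen_lfp_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def modulated_pair():
    """60-s noiseless pair with both gamma bands power-modulated at m=0.5.

    Shared by the closed-form coupling tests; matched band modulation keeps
    cross-band wavelet leakage carrying the same raised cosine.
    """
    config = SyntheticConfig(
        mod_depth_slow=0.5, mod_depth_fast=0.5,
        preferred_phase_slow=0.0, preferred_phase_fast=0.0,
        noise_amp=0.0,
    )
    vhpc, mpfc, truth = gen_lfp_pair(config, seed=7, duration=60.0)
    return config, vhpc, mpfc, truth
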