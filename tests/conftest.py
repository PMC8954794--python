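import pytest

from ssbnmr import simulate as sim


@pytest.fixture(scope="session")
def cfg():
    """Default study-condition simulation config (1% noise)."""
    return sim.SimulationConfig()


@pytest.fixture(scope="session")
def truth(cfg):
    return sim.default_ground_truth(cfg)


@pytest.fixture(scope="session")
def quiet_cfg():
    """Zero-noise config: generator outputs are exact forward-model values."""
    return sim.SimulationConfig(noise_sd=0.0, shift_noise_h_ppm=0.0,
                                shift_noise_n_ppm=0.0)


@pytest.fixture(scope="session")
def quiet_truth(quiet_cfg):
    return sim.default_ground_truth(quiet_cfg)
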