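import pytest

from myoflow import FrameSchedule, SimConfig, simulate_study


@pytest.fixture(scope="session")
def spect_schedule():
    return FrameSchedule.spect_32frame()


@pytest.fixture(scope="session")
def pet_schedule():
    return FrameSchedule.pet_24frame()


@pytest.fixture(scope="session")
def noiseless_config():
    """Small noiseless cohort with deterministically linked FFR."""
    return SimConfig(seed=42, n_patients=3, noise_scale=0.0,
                     ffr_perfectly_linked=True)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return simulate_study(noiseless_config)


@pytest.fixture(scope="session")
def noisy_study():
    return simulate_study(SimConfig(seed=11, n_patients=3))
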