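import pytest

from cploc import observer, synth_eeg, task


@pytest.fixture(scope="session")
def default_cfg() -> task.TaskConfig:
    return task.TaskConfig()


@pytest.fixture(scope="session")
def a_params() -> observer.ObserverParams:
    """Audio-only observer: sensory noise at the experimental-noise scale."""
    return observer.ObserverParams(sensory_noise_sd=10.0)


@pytest.fixture(scope="session")
def layout16() -> synth_eeg.ChannelLayout:
    return synth_eeg.make_layout(16)
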