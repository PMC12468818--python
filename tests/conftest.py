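import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """A small synthetic corpus shared across tests: 4 speakers x 6 clips,
    short clips to keep I/O light."""
    from painspeech.synth import SynthConfig, synth_corpus

    out = tmp_path_factory.mktemp("tiny_corpus")
    config = SynthConfig(
        n_speakers=4, clips_per_speaker=8, duration_mean=1.2, duration_sd=0.2, seed=9
    )
    table = synth_corpus(config, out)
    return config, table, out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
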