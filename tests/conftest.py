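import numpy as np
import pytest

from qrstangle.synthetic_data import SyntheticBeatSpec, generate_record


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free, single-dipole-per-phase synthetic record."""
    spec = SyntheticBeatSpec(alpha_true=60.0, loop_spread=0.0, noise_sd=0.0, seed=7)
    return generate_record(spec, record_id="clean")


@pytest.fixture(scope="session")
def noisy_record():
    spec = SyntheticBeatSpec(alpha_true=95.0, seed=11)
    return generate_record(spec, record_id="noisy")
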