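import numpy as np
import pytest

from limbrqa.preprocessing import preprocess_session
from limbrqa.synthetic import RegimeParams, generate_session


@pytest.fixture(scope="session")
def rhythmic_session():
    """50 s rhythmic four-limb session at the full 60 Hz rate."""
    return generate_session(RegimeParams("rhythmic", 50.0), seed=11, rate_hz=60.0)


@pytest.fixture(scope="session")
def rhythmic_series(rhythmic_session):
    return preprocess_session(rhythmic_session)


@pytest.fixture(scope="session")
def unstructured_session():
    return generate_session(
        RegimeParams("unstructured", 50.0), seed=12, rate_hz=60.0
    )


@pytest.fixture(scope="session")
def small_states(rhythmic_session):
    """A modest embedded state matrix for recurrence tests (12 Hz profile)."""
    from limbrqa.embedding import embed_multidim

    session = generate_session(RegimeParams("rhythmic", 25.0), seed=3, rate_hz=12.0)
    return embed_multidim(preprocess_session(session), tau=1, m=4)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
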