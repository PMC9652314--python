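import numpy as np
import pytest

from spacedilemma import generate_dyad, session_features


@pytest.fixture(scope="session")
def b6_params():
    return {"precision": 20.0, "social_bias": 0.1, "titxtat": 0.8,
            "q_risk": 0.5}


@pytest.fixture(scope="session")
def dyad_session(b6_params):
    """A deterministic full session between two mid-range Bayesian players."""
    other = {"precision": 30.0, "social_bias": 0.15, "titxtat": 0.6,
             "q_risk": 1.0}
    return generate_dyad("B6", b6_params, "B6", other, seed=42,
                         dyad_id="fixture")


@pytest.fixture(scope="session")
def features_p1(dyad_session):
    return session_features(dyad_session, player=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
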