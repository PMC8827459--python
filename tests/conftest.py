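import pytest

from erythemawave import KineticParams, steady_states


@pytest.fixture(scope="session")
def strong_feedback():
    """Strongly bistable kinetics (deep inflamed state), as in the circular
    expansion scenario."""
    return KineticParams(a=4.0, b=0.01, n=2, d=0.5)


@pytest.fixture(scope="session")
def moderate_feedback():
    """Moderate bistability: expanding front with a comfortably positive
    theoretical velocity."""
    return KineticParams(a=2.14, b=0.05, n=2, d=0.5)


@pytest.fixture(scope="session")
def weak_feedback():
    """Weak positive feedback: threshold closer to the inflamed state, so the
    front reverses and the inflamed area shrinks."""
    return KineticParams(a=1.96, b=0.05, n=2, d=0.5)


@pytest.fixture(scope="session")
def strong_ss(strong_feedback):
    return steady_states(strong_feedback)


@pytest.fixture(scope="session")
def moderate_ss(moderate_feedback):
    return steady_states(moderate_feedback)


@pytest.fixture(scope="session")
def weak_ss(weak_feedback):
    return steady_states(weak_feedback)
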