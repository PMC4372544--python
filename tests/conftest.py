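import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def simplex_vectors(draw, min_r=2, max_r=6):
    """Random compositions: non-degenerate points on the simplex."""
    r = draw(st.integers(min_r, max_r))
    raw = draw(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=r, max_size=r).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    x = np.asarray(raw)
    return x / x.sum()


@st.composite
def weight_vectors(draw, r):
    raw = draw(st.lists(st.floats(0.0, 5.0, allow_nan=False), min_size=r, max_size=r))
    return np.asarray(raw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_setup():
    """The standard three-group study conditions."""
    import biofilmdrift as bd

    return {
        "init": bd.DiscreteState.from_composition((0.2, 0.8, 0.0), 1000),
        "sel": bd.SelectionParams.neutral(3),
        "mig": bd.MigrationParams(m=0.04, p=np.array([0.0, 0.0, 1.0])),
        "N": 1000,
    }
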