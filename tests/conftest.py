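import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def blosum62():
    from cggtools.align import load_matrix

    return load_matrix("BLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length):
    from cggtools.io import STANDARD_AA

    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture()
def small_proteome():
    """10 background records, one Q-tract implant, one fusion trio, one
    family group — the workhorse fixture."""
    from cggtools.fixtures import FixtureSpec, make_fixture

    return make_fixture(
        FixtureSpec(
            n_sequences=10,
            length_range=(80, 160),
            seed=7,
            lcr_implants=[(0, 11, 30, "Q")],
            fusion_trios=1,
            family_groups=1,
        )
    )
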