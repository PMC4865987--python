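import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampliscreen.simulate import PAPER_SCALE, TINY, generate_panel_fixture, generate_reference

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_reference():
    return generate_reference(11, n_chrom=2, chrom_len=400_000)


@pytest.fixture(scope="session")
def tiny_fixture(tiny_reference):
    """(panel, amplicons) for the tiny structural preset."""
    return generate_panel_fixture(tiny_reference, TINY, 11)


@pytest.fixture(scope="session")
def paper_reference():
    return generate_reference(5)


@pytest.fixture(scope="session")
def paper_fixture(paper_reference):
    """(panel, amplicons) at the paper-scale structural preset."""
    return generate_panel_fixture(paper_reference, PAPER_SCALE, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
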