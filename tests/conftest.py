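import numpy as np
import pytest

from dielrhythm import generate_design
from dielrhythm.synthetic import OrganSpec, SharingSpec, generate_multi_organ


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def times(design):
    return np.asarray(design.sample_times_zt)


@pytest.fixture(scope="session")
def small_multi_organ(design):
    """A small 3-organ dataset with defaults scaled down for unit tests."""
    specs = {
        o: OrganSpec(n_transcripts=300, rhythmic_fraction=0.3)
        for o in ("L1", "I1", "I5")
    }
    return generate_multi_organ(design, specs, SharingSpec(), rng_seed=42)
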