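import numpy as np
import pytest

import mcwr


@pytest.fixture
def leslie_schedule():
    """4-age-class schedule with late-peaking fertility."""
    survival = np.array([0.9, 0.8, 0.7, 0.0])
    fertility = np.array([0.0, 0.5, 1.2, 2.0])
    return survival, fertility


@pytest.fixture
def leslie_model(leslie_schedule):
    return mcwr.leslie_from_schedule(*leslie_schedule)


@pytest.fixture
def stage_u():
    """Synthetic 6-stage perennial with stasis and retrogression."""
    return mcwr.paper_fixture("trillium_like_u")


@pytest.fixture
def overdispersed_cohort():
    """Per-stage reproduction samples, only the last stage reproducing,
    index of dispersion ~6."""
    return mcwr.synthetic_cohort([0, 0, 0, 0, 0, 8.0], dispersion=6,
                                 n_individuals=5000, seed=11)
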