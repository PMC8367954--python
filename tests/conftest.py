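import numpy as np
import pytest

import eegmicrostates as em


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def templates110():
    """Five well-separated ground-truth maps on a 110-channel layout."""
    return em.make_templates(110, 5, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused across tests (5+5 subjects, 60 s)."""
    cfg = em.SimConfig(duration_s=60.0, group_sizes={"ASD": 5, "TD": 5},
                       rng_seed=11)
    return em.simulate_cohort(cfg)


@pytest.fixture
def simple_recording(rng):
    """A 6-channel, 500-sample random recording, average-referenced."""
    rec = em.EEGRecording(data=rng.normal(0, 10, (6, 500)), srate=125.0)
    return em.rereference_average(rec)
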