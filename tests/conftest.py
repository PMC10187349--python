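import pytest

from tgfbsig import synthdata as sd


@pytest.fixture(scope="session")
def coculture_default():
    """One default co-culture simulation shared across tests."""
    cfg = sd.CoCultureConfig(seed=11)
    return cfg, *sd.simulate_coculture(cfg)


@pytest.fixture(scope="session")
def cohort_default():
    """One default repeated-biopsy cohort shared across tests."""
    cfg = sd.CohortConfig(seed=11)
    return cfg, *sd.simulate_cohort(cfg)
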