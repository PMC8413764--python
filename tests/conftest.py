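import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject cohort, short scans: enough for smoke-level pipelines."""
    from dynstates.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_patients=3,
        n_controls=3,
        n_timepoints=80,
        n_discard=5,
        n_states=2,
        seed=7,
    )
    return generate_cohort(cfg)
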