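import numpy as np
import pytest

import nestmi as nm


@pytest.fixture(scope="session")
def small_spec():
    return nm.default_cohort_spec(n_subjects=400)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return nm.generate_full_panel(small_spec, seed=1234)


@pytest.fixture(scope="session")
def masked_panel(small_panel):
    """Panel with scenario-1 MAR + MNAR missingness (no deaths)."""
    mar = nm.generate_mar_missingness(small_panel, nm.default_mar_spec(), seed=21)
    mnar = nm.generate_mnar_nonattendance(
        small_panel, nm.MnarScenario(scenario_id=1), seed=22
    )
    return small_panel, mar.merge(mnar)


@pytest.fixture(scope="session")
def survival_setup(small_panel):
    surv = nm.default_survival_spec()
    events = nm.generate_event_times(small_panel, surv, seed=31)
    return surv, events


def rng(seed=0):
    return np.random.default_rng(seed)
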