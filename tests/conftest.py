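import numpy as np
import pytest

from capdce import (
    SimulationConfig,
    load_fixture,
    optimize_design,
    simulate_choices,
)

#: Published pilot point estimates used as a plausible true coefficient vector
#: (payment_schedule, timeliness, rate, services, performance, opt-out ASC).
PILOT_BETA = np.array([-0.0895, 0.4808, 0.0003, -0.0360, 0.0540, -0.2319])

#: Code spans of the pilot attributes (max - min level code).
PILOT_SPANS = {
    "payment_schedule": 11.0,
    "payment_timeliness": 1.0,
    "capitation_rate": 3600.0,
    "services_covered": 3.0,
    "performance_requirements": 1.0,
}


@pytest.fixture(scope="session")
def pilot_attrs():
    return load_fixture("pilot")


@pytest.fixture(scope="session")
def final_attrs():
    return load_fixture("final")


@pytest.fixture(scope="session")
def pilot_design(pilot_attrs):
    design, _ = optimize_design(pilot_attrs, n_tasks=8, n_nonoptout_alts=2,
                                seed=11, n_starts=3)
    return design


@pytest.fixture(scope="session")
def pilot_data(pilot_design):
    """Pilot-shaped simulated panel: 31 respondents x 8 tasks x 3 alts."""
    cfg = SimulationConfig(beta_true=PILOT_BETA, n_respondents=31, seed=7)
    return simulate_choices(pilot_design, cfg)


@pytest.fixture(scope="session")
def big_data(pilot_design):
    """Large panel for parameter-recovery checks (500 respondents)."""
    cfg = SimulationConfig(beta_true=PILOT_BETA, n_respondents=500, seed=13)
    return simulate_choices(pilot_design, cfg)
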