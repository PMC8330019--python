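import numpy as np
import pytest
from hypothesis import settings

from phenoresp.response_rules import ResponseRuleSet, VisitRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from phenoresp.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def rules():
    return ResponseRuleSet()


def make_visits(pid="P1", fev1=(0.80, 0.92, 0.95, 0.90),
                mef50=(0.85, 1.05, 1.00, 0.95),
                feno=(20.0, 25.0, 18.0, 12.0),
                ctrl=(1, 0, 0, 1), n_visits=4):
    """Helper building a complete (or truncated) four-visit patient."""
    return [
        VisitRecord(patient_id=pid, visit_index=i, fev1_pp=fev1[i],
                    mef50_pp=mef50[i], feno_ppb=feno[i], control_level=ctrl[i])
        for i in range(n_visits)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort at the default study conditions.

    365 enrolled, archetype proportions scaled, deterministic missingness
    (18 patients lose one late visit), noise 0.  Session-scoped: several
    test modules reuse it.
    """
    config = SimulationConfig(seed=7)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def complete_cohort():
    """A complete-case cohort of 347 with exact archetype sizes, noise 0."""
    config = SimulationConfig(n_enrolled=347, missing_rate=0.0, seed=11)
    return config, simulate_cohort(config)
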