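import pytest
from hypothesis import settings

import studyqc as q
from studyqc.simulate import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return q.example_schema()


@pytest.fixture(scope="session")
def study():
    """One simulated study shared across the suite (default conditions)."""
    return simulate_study(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def records(study):
    result = study.ingest()
    assert result.n_violations == 0
    return result.records


@pytest.fixture(scope="session")
def flags(study, records):
    return q.run_checks(records, study.registry, study.schema)


@pytest.fixture(scope="session")
def statuses(study, records, flags):
    return q.form_status_table(records, flags, study.schema)
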