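import pytest

from emaqc import GeneratorConfig, enrich_assessments, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized synthetic cohort at generator defaults, shared read-only."""
    config = GeneratorConfig(n_participants=250, seed=20240412)
    participants, assessments, truth = simulate_cohort(config)
    return config, participants, assessments, truth


@pytest.fixture(scope="session")
def enriched_default(default_cohort):
    _, participants, assessments, truth = default_cohort
    return participants, enrich_assessments(assessments), truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with zero injected careless behaviour (false-positive guard)."""
    config = GeneratorConfig(
        n_participants=150,
        seed=7,
        careless_fraction_fast=0.0,
        careless_fraction_straightline=0.0,
    )
    participants, assessments, truth = simulate_cohort(config)
    return participants, enrich_assessments(assessments), truth
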