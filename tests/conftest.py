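import pytest

from magee_triage import (
    PathologyInput,
    SimulationParams,
    compute_magee_scores,
    generate_cohort,
    generate_survival,
)

# the reference case: 2.0 cm grade II (Nottingham 6, mitosis 1) tumor,
# ER H-score 300, PR H-score 0, HER2-negative, Ki-67 15%
WORKED_EXAMPLE = dict(
    tumor_size=2.0,
    nottingham_score=6,
    mitosis_score=1,
    er_h_score=300,
    pr_h_score=0,
    her2_status="negative",
    ki67_index=15,
)


@pytest.fixture(scope="session")
def worked_example_input():
    return PathologyInput(**WORKED_EXAMPLE)


@pytest.fixture(scope="session")
def worked_example_scores(worked_example_input):
    return compute_magee_scores(worked_example_input)


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded default synthetic cohort (n=2196) with survival annotations."""
    params = SimulationParams()
    cohort = generate_survival(generate_cohort(params, seed=0), params, seed=1)
    return [c.record for c in cohort]


@pytest.fixture(scope="session")
def default_synthetic(default_cohort):
    # alias clarifying intent where only pathology fields matter
    return default_cohort
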