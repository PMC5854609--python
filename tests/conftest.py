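import pytest

from neoscreen import SyntheticCohortConfig, generate_all


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort used by most integration tests."""
    cfg = SyntheticCohortConfig(
        seed=7, n_patients=6, mutation_bounds=(10, 30), n_proteins=30,
        n_pbl_responders=3, n_til_patients=4, n_til_responders=2,
        reads_per_compartment=20_000,
    )
    return generate_all(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full 19-patient cohort under the default study-like conditions."""
    return generate_all(SyntheticCohortConfig(seed=1))
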