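import pytest
from hypothesis import HealthCheck, settings

from lfqpair import PsmRecord, SimConfig, analyze_experiment, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_psm(
    peptide_seq="ELVISLIVESK",
    accessions=("P00001",),
    donor_id="d1",
    condition="CTL",
    fraction=1,
    charge=2,
    peptide_log_e=-3.0,
    fragment_intensity=1000.0,
):
    """Shorthand for building valid PSM records in tests."""
    return PsmRecord(
        donor_id=donor_id,
        condition=condition,
        fraction=fraction,
        peptide_seq=peptide_seq,
        charge=charge,
        protein_accessions=tuple(accessions),
        peptide_log_e=peptide_log_e,
        fragment_intensity=fragment_intensity,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated paired experiment shared across tests."""
    return simulate_experiment(SimConfig(n_proteins=300, seed=7))


@pytest.fixture(scope="session")
def small_result(small_sim):
    return analyze_experiment(small_sim.runs)
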