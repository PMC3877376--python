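import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from melprs.panel import default_panel

    return default_panel()


@pytest.fixture(scope="session")
def mdacc_cohort(panel):
    """A moderate discovery-style cohort simulated under the default truth."""
    from melprs.synth import CohortConfig, simulate_case_control

    cfg = CohortConfig(n_cases=600, n_controls=600, panel=panel, seed=20240131)
    return simulate_case_control(cfg)


@pytest.fixture(scope="session")
def mdacc_prs(panel, mdacc_cohort):
    from melprs.prs import compute_prs

    return compute_prs(mdacc_cohort[panel.snp_ids], panel)
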