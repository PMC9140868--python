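import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_example():
    from zwmarker.synthetic_data import paper_fixture

    return paper_fixture()


@pytest.fixture(scope="session")
def worked_example_result(worked_example):
    from zwmarker.pipeline import run_pipeline

    fx = worked_example
    return run_pipeline(fx.records, fx.mrnas, fx.primer_pairs, fx.role_map, species_id="Te")
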