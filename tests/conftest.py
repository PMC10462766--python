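import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import iciscreen as ic  # noqa: E402


@pytest.fixture(scope="session")
def worked_example():
    """Tiny fixed two-dataset database with hand-checkable statistics."""
    return ic.simulate_worked_example()


@pytest.fixture(scope="session")
def raw_combined(worked_example):
    """Worked example merged into the union gene space (no normalization)."""
    return ic.merge_datasets(worked_example.matrices)


@pytest.fixture(scope="session")
def worked_labels(worked_example):
    labels, _ = ic.label_cohort(worked_example.annotations)
    return labels


@pytest.fixture(scope="session")
def pd1_pre_cohort(worked_example, raw_combined, worked_labels):
    """Pre-treatment anti-PD-1 cohort of the worked example, raw values."""
    return ic.build_cohort(
        raw_combined,
        worked_example.annotations,
        worked_labels,
        ic.CohortSpec("anti-PD-1", "pre-treatment"),
    )


@pytest.fixture(scope="session")
def synthetic_db():
    """Default-configuration synthetic database (fixed seed)."""
    return ic.simulate_database(ic.default_config(seed=11))


@pytest.fixture(scope="session")
def synthetic_db_dir(synthetic_db, tmp_path_factory):
    """The synthetic database written to disk; returns the directory."""
    out = tmp_path_factory.mktemp("syndb")
    ic.write_database(synthetic_db, out)
    return out
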