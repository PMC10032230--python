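import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort: 6 subjects, 3 sessions, homes, proxy."""
    from rehabsense.synthetic import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(
        n_subjects=6,
        n_sessions=3,
        seed=1,
        home_records_per_subject=1,
        home_duration=120,
        long_rest_duration=40,
        n_proxy_subjects=4,
        proxy_minutes_per_subject=1.5,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_data(small_cohort):
    from rehabsense.pipeline import build_cohort_data

    return build_cohort_data(small_cohort)


@pytest.fixture(scope="session")
def bench_data():
    """The default benchmark cohort (canonical fixed seed), preprocessed."""
    from rehabsense.benchmark import benchmark_data

    return benchmark_data(seed=7)
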