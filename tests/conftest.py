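import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def probes():
    from gluscreen.fixtures import load_probes

    return load_probes()


@pytest.fixture(scope="session")
def study_tables():
    from gluscreen.fixtures import load_study_tables

    return load_study_tables()


@pytest.fixture(scope="session")
def small_benchmark():
    """Small screened benchmark shared by screen/topology tests."""
    from gluscreen.screen import run_screen
    from gluscreen.synthetic import (
        SyntheticSpec,
        generate_dataset,
        generate_lineage,
    )

    spec = SyntheticSpec(
        n_channels_group1=5,
        n_channels_group2=5,
        n_decoys_per_class=5,
        substitution_rate=0.05,
        rng_seed=1,
    )
    records, truths = generate_dataset(spec)
    lineage = generate_lineage(records, 1)
    result = run_screen(records, lineage)
    return spec, records, truths, lineage, result
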