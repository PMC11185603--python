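import pytest

from immunorank.fixtures import FixtureConfig, build_projects, simulate_project

#: compact study conditions used by most unit tests (fast to simulate)
SMALL = dict(
    n_genes=80, n_samples=6, n_phenotypes=2, n_positives=(4, 6),
    n_negatives=12, pos_pool_size=18, neg_pool_size=20,
)


@pytest.fixture(scope="session")
def small_data():
    return simulate_project(FixtureConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_projects(small_data):
    return build_projects(small_data)
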