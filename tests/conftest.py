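import pytest
from hypothesis import settings

from trionovo import SimParams, fixture_paper_cohort, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from trionovo.simulate import brain_gene_set


@pytest.fixture(scope="session")
def paper():
    return fixture_paper_cohort()


@pytest.fixture(scope="session")
def small_params():
    # small cohort: fast enough for unit tests, rich enough to hit every class
    return SimParams(
        n_trios=8,
        variants_per_proband=400,
        n_planted=1,
        planted_carrier_count=5,
        artifact_rate=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def small_sim_genes(small_sim):
    return brain_gene_set(small_sim)
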