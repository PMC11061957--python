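import numpy as np
import pytest

from nagpipe.simulate import Cohort, SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SMALL_CONFIG = SimConfig(
    seed=7,
    genome_names=("A", "B"),
    chromosomes=(("chr1", 300_000), ("chr20", 150_000)),
    n_templates=40,
    n_nags=15,
    n_decoy_overlap=4,
    n_decoy_lncrna=4,
    n_decoy_short=4,
)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A two-genome toy cohort shared by the integration tests."""
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    from nagpipe.pipeline import run_cohort

    return run_cohort(small_cohort)
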