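import warnings

import pytest

from tmeflow import PipelineConfig, generate_cohort
from tmeflow.synthetic import DEFAULT_CELL_TYPES

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions: 120 samples x 2000 genes,
    8 cell types, 60 TFs in 4 planted modules."""
    return generate_cohort(config=PipelineConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    return generate_cohort(
        n_samples=60, n_genes=800, cell_types=DEFAULT_CELL_TYPES[:6],
        n_tfs=30, targets_per_tf=10, config=PipelineConfig(rng_seed=5),
    )


@pytest.fixture()
def config():
    return PipelineConfig(rng_seed=0)
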