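import pytest

from germtriage import PipelineConfig, run_pipeline
from germtriage.genes import default_gene_lists
from germtriage.synthetic_data import CohortSizes, SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def gene_lists():
    return default_gene_lists()


@pytest.fixture(scope="session")
def sim_config():
    # study-sized case/control cohorts; comparison cohorts scaled down
    return SimulationConfig(seed=1, cohorts=CohortSizes(mgrb=300, ppcg_euro=300))


@pytest.fixture(scope="session")
def synthetic(sim_config):
    return simulate_cohorts(sim_config)


@pytest.fixture(scope="session")
def pipeline_result(synthetic):
    return run_pipeline(synthetic.bundle, PipelineConfig(), seed=1)
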