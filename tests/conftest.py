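import pytest

from claimlines import CodeConfig, run_pipeline
from claimlines.outcomes import CPITable
from claimlines.synthetic_claims import DATA_END, SimulationConfig, generate


@pytest.fixture(scope="session")
def codes():
    return CodeConfig()


@pytest.fixture(scope="session")
def cpi_identity():
    return CPITable.identity(range(2010, 2031))


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free generated dataset (n=250) with ground truth."""
    cfg = SimulationConfig(n_patients=250, seed=11).noise_free()
    dataset, truth = generate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def pipeline_small(small_cohort, codes, cpi_identity):
    """Full pipeline run on the small noise-free dataset."""
    cfg, dataset, truth = small_cohort
    results = run_pipeline(dataset, codes, cpi_identity, DATA_END)
    return cfg, dataset, truth, results
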