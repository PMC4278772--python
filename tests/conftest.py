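import pytest

from patseq.pipeline import PipelineConfig, run_pipeline
from patseq.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A desk-scale synthetic experiment: 40 genes, ~8k tags per sample."""
    return SimulationConfig(
        n_chromosomes=1, genes_per_chromosome=40, depth_per_sample=8000, seed=3
    )


@pytest.fixture(scope="session")
def small_run(small_sim_config, tmp_path_factory):
    """One full synthetic pipeline run shared by the pipeline tests."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(output_dir=out / "run", sim=small_sim_config, seed=3)
    return run_pipeline(cfg)
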