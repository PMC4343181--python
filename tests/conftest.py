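import pytest

from apapipe.pipeline import run_synthetic_pipeline
from apapipe.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic study conditions (seed 1)."""
    return run_synthetic_pipeline(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_world():
    """A small generated (genome, annotation, truth) for structural checks."""
    from apapipe.synthetic import generate_genome_and_annotation
    cfg = SimulationConfig(seed=7, n_genes=20, n_reads_per_tissue=4000)
    genome, annotation, truth = generate_genome_and_annotation(cfg)
    return cfg, genome, annotation, truth
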