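import numpy as np
import pytest

from pistarv.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    derive_contig_set,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_transcripts=120, library_depth=2500,
                            n_promoters=30)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    transcripts, truth = simulate_transcriptome(small_config)
    return transcripts, truth


@pytest.fixture(scope="session")
def small_contigs(small_config, small_experiment):
    transcripts, truth = small_experiment
    contigs = derive_contig_set(transcripts, truth, small_config)
    return contigs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
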