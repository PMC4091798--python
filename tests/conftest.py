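import numpy as np
import pytest

from crosstx.simulate import SimulationConfig, gen_probesets, gen_transcriptome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=1, n_genes=20, length_mean=300.0, length_sd=50.0,
                            min_length=100, n_probesets=30, off_target_fraction=0.3,
                            probe_divergence_rate=0.02)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    sequences, variants = gen_transcriptome(small_config)
    return sequences, variants


@pytest.fixture(scope="session")
def small_probes(small_config, small_transcriptome):
    sequences, _ = small_transcriptome
    library, truth = gen_probesets(sequences, small_config)
    return library, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
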