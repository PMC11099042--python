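import numpy as np
import pytest

from chromdyn.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """A desk-scale config that keeps every generator under a second."""
    return SimConfig(
        seed=7,
        n_peaks=600,
        genome={"chr1": 1_000_000, "chr2": 800_000},
        n_tf_peaks=200,
        n_tf_shared=80,
        n_decoy_genes=40,
        n_decoy_enhancers=40,
        n_background_seqs=100,
        binding_genome={"chrA": 1_500_000},
        n_genes=200,
        n_de_up=40,
        n_de_down=30,
        n_loops=300,
    )
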