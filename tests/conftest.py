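import numpy as np
import pytest

from hyenaselect import GenomeSequence, HyenaConfig, HyenaModel, segment_all


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    return HyenaConfig(
        l_in=32, d_model=16, n_layer=2, filter_mlp_hidden=8, pos_feat_dim=5,
        max_epochs=2, batch_size=4, seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return HyenaModel(tiny_config)


def make_windows(sequence: str, l_in: int, chrom: str = "chr01", sample: str = "s"):
    return segment_all(GenomeSequence(sample, chrom, sequence), l_in)


@pytest.fixture
def periodic_windows():
    return make_windows("ACGT" * 64, 32)
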