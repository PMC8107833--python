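import numpy as np
import pytest

from tcrpair import SignalSpec, SplitSpec, generate_repertoire
from tcrpair.encoders import SequenceEncoderSpec

# Small widths keep desk-scale training fast; the architecture (two stacked
# recurrent layers, sqrt-width MLP heads, 50-dim categorical embeddings) is
# unchanged from the defaults.
TINY_ACCEPTOR = SequenceEncoderSpec(kind="acceptor", acceptor_units=16)
TINY_AUTOENCODER = SequenceEncoderSpec(kind="autoencoder",
                                       autoencoder_hidden_dim=64,
                                       autoencoder_latent_dim=24)


@pytest.fixture(scope="session")
def small_repertoire():
    """300 positive pairs with strong beta-motif signal, mixed alpha missingness."""
    return generate_repertoire(SignalSpec(n_pairs=300, alpha_missing_rate=0.4,
                                          seed=11))


@pytest.fixture(scope="session")
def null_repertoire():
    """300 positive pairs with no implanted signal of any kind."""
    return generate_repertoire(SignalSpec(n_pairs=300, beta_motif_rate=0.0,
                                          alpha_missing_rate=0.4, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
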