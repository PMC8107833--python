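"""Fixed-length numeric encodings of CDR3/peptide sequences and categorical features.

Two sequence encoders are provided:

* **Acceptor encoding** -- residues pass through a learned 10-dimensional
  embedding and a two-layer stacked LSTM (dropout between the layers); the
  hidden state at each sequence's true final position is the encoding.
  Separate parameter sets are used for CDR3alpha, CDR3beta and the peptide.
* **Autoencoder encoding** -- sequences up to 28 residues are right-padded
  over a 21-symbol alphabet (20 residues + end/pad), one-hot flattened, and
  compressed to a latent vector by an encoder that is pretrained on
  unlabeled TCRs and fine-tuned with the classifier.

V/J genes and MHC alleles are categorical: each distinct value owns a row
of a learned 50-dimensional embedding matrix, with a reserved row shared by
missing and never-seen values. The T-cell compartment is a scalar flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .records import ABSENT, AMINO_ACIDS, Vocabulary

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
PAD_INDEX = len(AMINO_ACIDS)  # shared end/pad symbol
N_SYMBOLS = len(AMINO_ACIDS) + 1


@dataclass(frozen=True)
class SequenceEncoderSpec:
    kind: str = "acceptor"  # "acceptor" | "autoencoder"
    aa_embed_dim: int = 10
    acceptor_units: int = 500
    acceptor_layers: int = 2
    acceptor_dropout: float = 0.1
    autoencoder_hidden_dim: int = 300
    autoencoder_latent_dim: int = 100
    max_tcr_length: int = 28

    def validate(self) -> None:
        if self.kind not in ("acceptor", "autoencoder"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        for name in ("aa_embed_dim", "acceptor_units", "acceptor_layers",
                     "autoencoder_hidden_dim", "autoencoder_latent_dim",
                     "max_tcr_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.acceptor_dropout < 1.0:
            raise ValueError("acceptor_dropout must be in [0, 1)")


@dataclass(frozen=True)
class CategoricalEmbedderSpec:
    embed_dim: int = 50


def _uniform_init(rng: np.random.Generator, shape, scale: float) -> nn.Tensor:
    return nn.param(rng.uniform(-scale, scale, size=shape))


def _check_sequences(seqs) -> None:
    for s in seqs:
        if not s or any(c not in AA_INDEX for c in s):
            raise ValueError(f"invalid amino-acid sequence: {s!r}")


class AcceptorEncoder:
    """Stacked-LSTM sequence acceptor; output dim = ``spec.acceptor_units``."""

    def __init__(self, spec: SequenceEncoderSpec, seed: int, name: str = "acceptor"):
        spec.validate()
        self.spec = spec
        self.name = name
        H, E = spec.acceptor_units, spec.aa_embed_dim
        rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
        k = 1.0 / np.sqrt(H)
        # residue embeddings are randomly initialized at unit scale (the
        # ecosystem default for embedding tables); the small uniform init is
        # reserved for the recurrent weights
        self.params: dict[str, nn.Tensor] = {
            f"{name}.embed": nn.param(rng.standard_normal((N_SYMBOLS, E))),
        }
        for layer in range(spec.acceptor_layers):
            in_dim = E if layer == 0 else H
            self.params[f"{name}.Wx{layer}"] = _uniform_init(rng, (in_dim, 4 * H), k)
            self.params[f"{name}.Wh{layer}"] = _uniform_init(rng, (H, 4 * H), k)
            self.params[f"{name}.b{layer}"] = nn.param(np.zeros(4 * H))

    @property
    def output_dim(self) -> int:
        return self.spec.acceptor_units

    def encode(self, seqs: list[str], train: bool = False,
               rng: np.random.Generator | None = None) -> nn.Tensor:
        """Encode a batch; returns the hidden state at each true final position.

        Padded positions beyond a sequence's end never influence its
        selected output because the recurrence only runs forward in time.
        """
        _check_sequences(seqs)
        B = len(seqs)
        lengths = np.array([len(s) for s in seqs])
        T = int(lengths.max())
        idx = np.full((B, T), PAD_INDEX, dtype=np.intp)
        for b, s in enumerate(seqs):
            idx[b, : len(s)] = [AA_INDEX[c] for c in s]

        H = self.spec.acceptor_units
        p_drop = self.spec.acceptor_dropout
        inputs = [nn.embedding_lookup(self.params[f"{self.name}.embed"], idx[:, t])
                  for t in range(T)]
        for layer in range(self.spec.acceptor_layers):
            Wx = self.params[f"{self.name}.Wx{layer}"]
            Wh = self.params[f"{self.name}.Wh{layer}"]
            b = self.params[f"{self.name}.b{layer}"]
            h = nn.constant(np.zeros((B, H)))
            c = nn.constant(np.zeros((B, H)))
            outputs = []
            for t in range(T):
                gates = nn.add(nn.add(nn.matmul(inputs[t], Wx),
                                      nn.matmul(h, Wh)), b)
                gi, gf, gg, go = nn.hsplit(gates, 4)
                i_g, f_g, o_g = nn.sigmoid(gi), nn.sigmoid(gf), nn.sigmoid(go)
                g_g = nn.tanh(gg)
                c = nn.add(nn.mul(f_g, c), nn.mul(i_g, g_g))
                h = nn.mul(o_g, nn.tanh(c))
                outputs.append(h)
            is_last_layer = layer == self.spec.acceptor_layers - 1
            if not is_last_layer and train and p_drop > 0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                outputs = [nn.mul(o, nn.constant(
                    (rng.random((B, H)) >= p_drop) / (1.0 - p_drop)))
                    for o in outputs]
            inputs = outputs

        final = nn.constant(np.zeros((B, H)))
        for t in range(T):
            mask = (lengths - 1 == t).astype(float)[:, None]
            if mask.any():
                final = nn.add(final, nn.mul(inputs[t], nn.constant(mask)))
        return final


def one_hot_sequences(seqs: list[str], max_len: int) -> np.ndarray:
    """Right-padded one-hot matrix, flattened to (B, max_len * 21)."""
    _check_sequences(seqs)
    B = len(seqs)
    out = np.zeros((B, max_len, N_SYMBOLS))
    for b, s in enumerate(seqs):
        if len(s) > max_len:
            raise ValueError(
                f"sequence of length {len(s)} exceeds the {max_len}-residue cap")
        for t, c in enumerate(s):
            out[b, t, AA_INDEX[c]] = 1.0
        out[b, len(s):, PAD_INDEX] = 1.0
    return out.reshape(B, max_len * N_SYMBOLS)


class SequenceAutoencoder:
    """Fixed-length one-hot autoencoder; latent dim = ``spec.autoencoder_latent_dim``.

    The decoder emits one softmax per sequence position (pad symbol
    included), so reconstruction loss is mean per-position cross-entropy
    over all ``max_tcr_length`` slots.
    """

    def __init__(self, spec: SequenceEncoderSpec, seed: int, name: str = "ae"):
        spec.validate()
        self.spec = spec
        self.name = name
        D = spec.max_tcr_length * N_SYMBOLS
        Hh, L = spec.autoencoder_hidden_dim, spec.autoencoder_latent_dim
        rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
        def glorot(fan_in, fan_out):
            return _uniform_init(rng, (fan_in, fan_out), np.sqrt(6.0 / (fan_in + fan_out)))
        self.params: dict[str, nn.Tensor] = {
            f"{name}.enc_W1": glorot(D, Hh), f"{name}.enc_b1": nn.param(np.zeros(Hh)),
            f"{name}.enc_W2": glorot(Hh, L), f"{name}.enc_b2": nn.param(np.zeros(L)),
            f"{name}.dec_W1": glorot(L, Hh), f"{name}.dec_b1": nn.param(np.zeros(Hh)),
            f"{name}.dec_W2": glorot(Hh, D), f"{name}.dec_b2": nn.param(np.zeros(D)),
        }

    @property
    def output_dim(self) -> int:
        return self.spec.autoencoder_latent_dim

    def encode(self, seqs: list[str], train: bool = False,
               rng: np.random.Generator | None = None) -> nn.Tensor:
        x = nn.constant(one_hot_sequences(seqs, self.spec.max_tcr_length))
        h = nn.leaky_relu(nn.add(nn.matmul(x, self.params[f"{self.name}.enc_W1"]),
                                 self.params[f"{self.name}.enc_b1"]))
        return nn.leaky_relu(nn.add(nn.matmul(h, self.params[f"{self.name}.enc_W2"]),
                                    self.params[f"{self.name}.enc_b2"]))

    def decode_logits(self, latent: nn.Tensor) -> nn.Tensor:
        h = nn.leaky_relu(nn.add(nn.matmul(latent, self.params[f"{self.name}.dec_W1"]),
                                 self.params[f"{self.name}.dec_b1"]))
        return nn.add(nn.matmul(h, self.params[f"{self.name}.dec_W2"]),
                      self.params[f"{self.name}.dec_b2"])

    def reconstruction_loss(self, seqs: list[str]) -> nn.Tensor:
        logits = self.decode_logits(self.encode(seqs))
        B = len(seqs)
        T = self.spec.max_tcr_length
        targets = np.full((B, T), PAD_INDEX, dtype=np.intp)
        for b, s in enumerate(seqs):
            targets[b, : len(s)] = [AA_INDEX[c] for c in s]
        flat = nn.Tensor(logits.data.reshape(B * T, N_SYMBOLS), (logits,),
                         lambda g: logits._accumulate(g.reshape(B, T * N_SYMBOLS)))
        return nn.softmax_xent_rows(flat, targets.reshape(-1))

    def reconstruct(self, seqs: list[str]) -> list[str]:
        """Greedy per-position argmax decoding (pad symbol terminates)."""
        logits = self.decode_logits(self.encode(seqs)).data
        T = self.spec.max_tcr_length
        out = []
        for row in logits.reshape(len(seqs), T, N_SYMBOLS):
            chars = []
            for t in range(T):
                k = int(row[t].argmax())
                if k == PAD_INDEX:
                    break
                chars.append(AMINO_ACIDS[k])
            out.append("".join(chars))
        return out


def pretrain_autoencoder(tcrs: list[str], spec: SequenceEncoderSpec | None = None,
                         epochs: int = 100, seed: int = 0, batch_size: int = 64,
                         lr: float = 1e-3, name: str = "ae"
                         ) -> tuple[SequenceAutoencoder, list[float]]:
    """Train a fresh autoencoder on an unlabeled TCR corpus.

    Returns the trained model and the per-epoch mean reconstruction loss.
    The returned parameters remain trainable, so a downstream classifier
    fine-tunes them by including them in its optimizer.
    """
    if not tcrs:
        raise ValueError("empty pretraining corpus")
    if spec is None:
        spec = SequenceEncoderSpec(kind="autoencoder")
    model = SequenceAutoencoder(spec, seed=seed, name=name)
    opt = nn.Adam(model.params, lr=lr, weight_decay=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    losses = []
    for _ in range(epochs):
        order = rng.permutation(len(tcrs))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(tcrs), batch_size):
            batch = [tcrs[i] for i in order[lo: lo + batch_size]]
            loss = model.reconstruction_loss(batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return model, losses


class CategoricalEmbedder:
    """Learned embedding rows for one categorical field (V/J gene or MHC)."""

    def __init__(self, vocabulary: Vocabulary, spec: CategoricalEmbedderSpec,
                 seed: int, name: str | None = None):
        if spec.embed_dim < 1:
            raise ValueError("embed_dim must be positive")
        self.vocabulary = vocabulary
        self.spec = spec
        self.name = name or vocabulary.field_name
        rng = np.random.default_rng(np.random.SeedSequence([seed, 24]))
        self.params = {f"{self.name}.embed": nn.param(
            rng.standard_normal((len(vocabulary), spec.embed_dim)))}

    @property
    def output_dim(self) -> int:
        return self.spec.embed_dim

    def encode(self, values: list[str]) -> nn.Tensor:
        idx = np.array([self.vocabulary.lookup(v) for v in values], dtype=np.intp)
        return nn.embedding_lookup(self.params[f"{self.name}.embed"], idx)


def encode_t_cell_type(t: str) -> np.ndarray:
    """CD4 -> 1.0, CD8 -> 0.0, absent -> 0.5 (least-informative midpoint)."""
    if t == "CD4":
        return np.array([1.0])
    if t == "CD8":
        return np.array([0.0])
    if t == ABSENT:
        return np.array([0.5])
    raise ValueError(f"unknown T-cell type {t!r}")
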