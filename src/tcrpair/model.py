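"""Dynamic-configuration binding classifier with dual MLP heads.

Active feature encodings are concatenated in a fixed order and fed to a
one-hidden-layer MLP whose hidden width is the square root of its input
width. Missing alpha chains are handled architecturally: records carrying a
CDR3alpha are routed to MLP-II (whose input includes the alpha-derived
blocks) and records without one to MLP-I (whose input excludes them); the
two heads share every encoder but none of their own weights, and the
weighted binary cross-entropy is accumulated across both heads in each
batch before the optimizer step.

Training follows the reference recipe: Adam (lr 1e-4, L2 1e-5), batches of
128 (train) / 64 (validation), loss weights 5/6 (positives) and 1/6
(negatives) matching the 1:5 positive:negative sampling ratio, and early
stopping after three consecutive epochs of decreasing validation AUC, with
the best-validation-AUC parameters returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoders import (AcceptorEncoder, CategoricalEmbedderSpec,
                       CategoricalEmbedder, SequenceAutoencoder,
                       SequenceEncoderSpec, encode_t_cell_type)
from .evaluation import compute_auc
from .records import ABSENT, PairRecord, Vocabulary, build_vocabulary

logger = logging.getLogger(__name__)

#: fixed concatenation order of feature blocks
CONCAT_ORDER = ("cdr3_beta", "cdr3_alpha", "v_beta", "j_beta", "v_alpha",
                "j_alpha", "mhc", "t_cell_type", "peptide")

ALPHA_BLOCKS = ("cdr3_alpha", "v_alpha", "j_alpha")


@dataclass(frozen=True)
class FeatureConfig:
    """Which optional features are active; CDR3beta and peptide always are.

    V and J genes toggle together, and the alpha-chain V/J embeddings are
    active only when the alpha chain itself is.
    """

    use_alpha: bool = False
    use_vj: bool = False
    use_mhc: bool = False
    use_t_cell_type: bool = False
    tcr_encoder: str = "acceptor"  # "acceptor" | "autoencoder"

    def validate(self) -> None:
        if self.tcr_encoder not in ("acceptor", "autoencoder"):
            raise ValueError(f"unknown tcr_encoder {self.tcr_encoder!r}")


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_train: int = 128
    batch_val: int = 64
    pos_weight: float = 5.0 / 6.0
    neg_weight: float = 1.0 / 6.0
    early_stop_patience: int = 3
    max_epochs: int = 30
    strict_decrease: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if abs(self.pos_weight + self.neg_weight - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")


def mlp_hidden_width(input_dim: int) -> int:
    """Hidden units per head: floor of the square root of the input width."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    return max(1, math.isqrt(input_dim))


def weighted_bce(probs, labels, weights=(5.0 / 6.0, 1.0 / 6.0)) -> float:
    """Mean class-weighted binary cross-entropy on probabilities.

    ``weights`` is (positive weight, negative weight).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must be strictly inside (0, 1)")
    w = np.where(y == 1, weights[0], weights[1])
    return float(np.mean(w * -(y * np.log(p) + (1 - y) * np.log(1 - p))))


def early_stop_epoch(val_aucs: list[float], patience: int = 3,
                     strict: bool = True) -> int | None:
    """Index (1-based epoch) after which training stops, or None.

    Stops at the first epoch completing ``patience`` consecutive decreases
    of the validation AUC (strict by default).
    """
    run = 0
    for e in range(1, len(val_aucs)):
        dec = val_aucs[e] < val_aucs[e - 1] if strict else val_aucs[e] <= val_aucs[e - 1]
        run = run + 1 if dec else 0
        if run >= patience:
            return e + 1
    return None


class _MLPHead:
    def __init__(self, input_dim: int, seed: int, name: str,
                 dropout: float = 0.1, negative_slope: float = 0.01):
        hidden = mlp_hidden_width(input_dim)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        k1 = np.sqrt(1.0 / input_dim)
        k2 = np.sqrt(1.0 / hidden)
        self.input_dim = input_dim
        self.hidden_dim = hidden
        self.dropout = dropout
        self.negative_slope = negative_slope
        self.params = {
            f"{name}.W1": nn.param(rng.uniform(-k1, k1, (input_dim, hidden))),
            f"{name}.b1": nn.param(np.zeros(hidden)),
            f"{name}.W2": nn.param(rng.uniform(-k2, k2, (hidden, 1))),
            f"{name}.b2": nn.param(np.zeros(1)),
        }
        self.name = name

    def logits(self, x: nn.Tensor, train: bool,
               rng: np.random.Generator | None) -> nn.Tensor:
        h = nn.leaky_relu(nn.add(nn.matmul(x, self.params[f"{self.name}.W1"]),
                                 self.params[f"{self.name}.b1"]),
                          self.negative_slope)
        if train and self.dropout > 0:
            mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = nn.mul(h, nn.constant(mask))
        return nn.add(nn.matmul(h, self.params[f"{self.name}.W2"]),
                      self.params[f"{self.name}.b2"])


class BinderModel:
    """Configurable TCR-pMHC binding classifier.

    Parameters
    ----------
    config:
        Active features and TCR sequence-encoder kind.
    vocabularies:
        One :class:`Vocabulary` per active categorical field, built from the
        training records so test-only values resolve to the unknown row.
    pretrained_beta_ae, pretrained_alpha_ae:
        Optional pretrained autoencoders (autoencoder mode); fresh randomly
        initialized ones are created when omitted. Their parameters join the
        classifier's optimizer and are fine-tuned.
    """

    def __init__(self, config: FeatureConfig,
                 vocabularies: dict[str, Vocabulary] | None = None,
                 records: list[PairRecord] | None = None,
                 encoder_spec: SequenceEncoderSpec | None = None,
                 categorical_spec: CategoricalEmbedderSpec | None = None,
                 seed: int = 0,
                 pretrained_beta_ae: SequenceAutoencoder | None = None,
                 pretrained_alpha_ae: SequenceAutoencoder | None = None):
        config.validate()
        self.config = config
        self.seed = seed
        spec = encoder_spec or SequenceEncoderSpec(kind=config.tcr_encoder)
        self.encoder_spec = spec
        cat_spec = categorical_spec or CategoricalEmbedderSpec()

        if vocabularies is None:
            if records is None and (config.use_vj or config.use_mhc):
                raise ValueError("need vocabularies or records for categorical features")
            vocabularies = {}
            needed = []
            if config.use_vj:
                needed += ["v_beta", "j_beta"]
                if config.use_alpha:
                    needed += ["v_alpha", "j_alpha"]
            if config.use_mhc:
                needed.append("mhc")
            for f in needed:
                vocabularies[f] = build_vocabulary(records, f)
        self.vocabularies = vocabularies

        self.peptide_encoder = AcceptorEncoder(
            SequenceEncoderSpec(kind="acceptor",
                                aa_embed_dim=spec.aa_embed_dim,
                                acceptor_units=spec.acceptor_units,
                                acceptor_layers=spec.acceptor_layers,
                                acceptor_dropout=spec.acceptor_dropout),
            seed=seed + 1, name="pep")
        if config.tcr_encoder == "acceptor":
            self.beta_encoder = AcceptorEncoder(spec, seed=seed + 2, name="beta")
            self.alpha_encoder = (AcceptorEncoder(spec, seed=seed + 3, name="alpha")
                                  if config.use_alpha else None)
        else:
            self.beta_encoder = pretrained_beta_ae or SequenceAutoencoder(
                spec, seed=seed + 2, name="beta_ae")
            self.alpha_encoder = None
            if config.use_alpha:
                self.alpha_encoder = pretrained_alpha_ae or SequenceAutoencoder(
                    spec, seed=seed + 3, name="alpha_ae")

        self.cat_embedders: dict[str, CategoricalEmbedder] = {}
        for i, f in enumerate(sorted(self.vocabularies)):
            self.cat_embedders[f] = CategoricalEmbedder(
                self.vocabularies[f], cat_spec, seed=seed + 10 + i, name=f)

        base_dim = self._block_dims(include_alpha=False)
        self.mlp1 = _MLPHead(base_dim, seed=seed + 20, name="mlp1")
        self.mlp2 = None
        if config.use_alpha:
            self.mlp2 = _MLPHead(self._block_dims(include_alpha=True),
                                 seed=seed + 21, name="mlp2")

        self.params: dict[str, nn.Tensor] = {}
        for comp in self._components():
            self.params.update(comp.params)

    def _components(self):
        comps = [self.peptide_encoder, self.beta_encoder]
        if self.alpha_encoder is not None:
            comps.append(self.alpha_encoder)
        comps += list(self.cat_embedders.values())
        comps.append(self.mlp1)
        if self.mlp2 is not None:
            comps.append(self.mlp2)
        return comps

    def _block_dims(self, include_alpha: bool) -> int:
        dims = {
            "cdr3_beta": self.beta_encoder.output_dim,
            "peptide": self.peptide_encoder.output_dim,
            "t_cell_type": 1,
        }
        total = 0
        for block in CONCAT_ORDER:
            if block in ("cdr3_beta", "peptide"):
                total += dims[block]
            elif block == "cdr3_alpha":
                if self.config.use_alpha and include_alpha:
                    total += self.alpha_encoder.output_dim
            elif block in ("v_beta", "j_beta"):
                if self.config.use_vj:
                    total += self.cat_embedders[block].output_dim
            elif block in ("v_alpha", "j_alpha"):
                if self.config.use_vj and self.config.use_alpha and include_alpha:
                    total += self.cat_embedders[block].output_dim
            elif block == "mhc":
                if self.config.use_mhc:
                    total += self.cat_embedders["mhc"].output_dim
            elif block == "t_cell_type":
                if self.config.use_t_cell_type:
                    total += 1
        return total

    def input_dim(self, with_alpha: bool) -> int:
        return self._block_dims(include_alpha=with_alpha)

    def concat_encodings(self, records: list[PairRecord], include_alpha: bool,
                         train: bool = False,
                         rng: np.random.Generator | None = None) -> nn.Tensor:
        """Concatenate active feature blocks in the fixed order."""
        if include_alpha:
            if not self.config.use_alpha:
                raise RuntimeError("alpha blocks requested but use_alpha is off")
            if any(not r.has_alpha() for r in records):
                raise RuntimeError("alpha-routing violated: record lacks CDR3alpha")
        blocks: list[nn.Tensor] = []
        for block in CONCAT_ORDER:
            if block == "cdr3_beta":
                blocks.append(self.beta_encoder.encode(
                    [r.cdr3_beta for r in records], train=train, rng=rng))
            elif block == "peptide":
                blocks.append(self.peptide_encoder.encode(
                    [r.peptide for r in records], train=train, rng=rng))
            elif block == "cdr3_alpha":
                if self.config.use_alpha and include_alpha:
                    blocks.append(self.alpha_encoder.encode(
                        [r.cdr3_alpha for r in records], train=train, rng=rng))
            elif block in ("v_beta", "j_beta", "v_alpha", "j_alpha", "mhc"):
                active = block in self.cat_embedders and (
                    block == "mhc" or self.config.use_vj)
                if block in ("v_alpha", "j_alpha"):
                    active = active and self.config.use_alpha and include_alpha
                if active:
                    blocks.append(self.cat_embedders[block].encode(
                        [getattr(r, block) for r in records]))
            elif block == "t_cell_type":
                if self.config.use_t_cell_type:
                    blocks.append(nn.constant(np.vstack(
                        [encode_t_cell_type(r.t_cell_type) for r in records])))
        return nn.concat(blocks, axis=1)

    def _route(self, records: list[PairRecord]) -> tuple[list[int], list[int]]:
        """Indices routed to MLP-I (no alpha) and MLP-II (alpha present)."""
        if self.mlp2 is None:
            return list(range(len(records))), []
        idx2 = [i for i, r in enumerate(records) if r.has_alpha()]
        idx1 = [i for i, r in enumerate(records) if not r.has_alpha()]
        return idx1, idx2

    def batch_logits(self, records: list[PairRecord], train: bool = False,
                     rng: np.random.Generator | None = None
                     ) -> list[tuple[list[int], nn.Tensor]]:
        """Per-head logits with the original record indices they cover."""
        idx1, idx2 = self._route(records)
        out = []
        if idx1:
            x = self.concat_encodings([records[i] for i in idx1],
                                      include_alpha=False, train=train, rng=rng)
            out.append((idx1, self.mlp1.logits(x, train, rng)))
        if idx2:
            x = self.concat_encodings([records[i] for i in idx2],
                                      include_alpha=True, train=train, rng=rng)
            out.append((idx2, self.mlp2.logits(x, train, rng)))
        return out

    def predict(self, records: list[PairRecord],
                batch_size: int = 64) -> np.ndarray:
        """Binding probabilities in (0, 1), deterministic (dropout off)."""
        probs = np.empty(len(records))
        for lo in range(0, len(records), batch_size):
            chunk = records[lo: lo + batch_size]
            for idx, logits in self.batch_logits(chunk, train=False):
                z = logits.data[:, 0]
                probs[lo + np.asarray(idx)] = 1.0 / (1.0 + np.exp(-z))
        return np.clip(probs, 1e-12, 1.0 - 1e-12)

    def batch_loss(self, records: list[PairRecord], spec: TrainSpec,
                   rng: np.random.Generator) -> nn.Tensor:
        """Weighted BCE accumulated over both heads, normalized by batch size."""
        n = len(records)
        labels = np.array([r.label for r in records], dtype=float)
        total: nn.Tensor | None = None
        for idx, logits in self.batch_logits(records, train=True, rng=rng):
            y = labels[idx][:, None]
            w = np.where(y == 1, spec.pos_weight, spec.neg_weight) * len(idx) / n
            part = nn.weighted_bce_logits(logits, y, w)
            total = part if total is None else nn.add(total, part)
        return total

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()


@dataclass
class TrainResult:
    model: BinderModel
    log: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_val_auc: float = float("nan")
    stopped_early: bool = False


def filter_max_length(records: list[PairRecord], max_len: int
                      ) -> list[PairRecord]:
    """Drop records whose CDR3 exceeds the fixed-length cap (logged count)."""
    out = [r for r in records
           if len(r.cdr3_beta) <= max_len
           and (r.cdr3_alpha == ABSENT or len(r.cdr3_alpha) <= max_len)]
    if len(out) < len(records):
        logger.info("filtered %d records with CDR3 longer than %d residues",
                    len(records) - len(out), max_len)
    return out


def train(train_records: list[PairRecord], val_records: list[PairRecord],
          model: BinderModel, spec: TrainSpec) -> TrainResult:
    """Fit the classifier; returns best-validation-AUC parameters and a log.

    Validation AUC is computed each epoch on ``val_records``; training stops
    after ``early_stop_patience`` consecutive decreasing epochs or at
    ``max_epochs``. In autoencoder mode, over-length CDR3 records are
    filtered from both sets up front.
    """
    spec.validate()
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    if model.config.tcr_encoder == "autoencoder":
        cap = model.encoder_spec.max_tcr_length
        train_records = filter_max_length(train_records, cap)
        val_records = filter_max_length(val_records, cap)
    val_labels = [r.label for r in val_records]
    if len(set(val_labels)) < 2:
        raise ValueError("validation set must contain both classes (AUC undefined)")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 41]))
    opt = nn.Adam(model.params, lr=spec.learning_rate,
                  weight_decay=spec.weight_decay)
    result = TrainResult(model=model)
    val_aucs: list[float] = []
    best_state = model.state_dict()
    best_auc = -np.inf
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(train_records))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), spec.batch_train):
            batch = [train_records[i] for i in order[lo: lo + spec.batch_train]]
            loss = model.batch_loss(batch, spec, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        scores = model.predict(val_records, batch_size=spec.batch_val)
        auc = compute_auc(val_labels, scores)
        val_aucs.append(auc)
        result.log.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                           "val_auc": auc})
        if auc > best_auc:
            best_auc = auc
            best_state = model.state_dict()
            result.best_epoch = epoch
        stop = early_stop_epoch(val_aucs, spec.early_stop_patience,
                                strict=spec.strict_decrease)
        if stop is not None:
            result.stopped_early = True
            break
    model.load_state_dict(best_state)
    result.best_val_auc = best_auc
    return result
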