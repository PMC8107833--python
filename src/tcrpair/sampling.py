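"""Train/test splitting, negative-pair sampling, and leakage-aware sieving.

Curated specificity databases contain only positive (binding) pairs, so
non-binding examples are manufactured by mismatching: a candidate negative
takes its TCR side (CDR3beta, CDR3alpha, V/J genes, T-cell type) from one
randomly drawn positive and its pMHC side (peptide, MHC) from another, and
is rejected if that TCR-peptide combination is itself a known positive.
Negatives outnumber positives 5:1 by default, in both train and test.

Because binding is a pairing problem, "outside the training set" depends on
which features the model saw: two records identical on the active features
are the same example even if they differ on inactive ones. The test sieve
removes any test record whose projection onto the active features collides
with a training record. On top of the sieve, each evaluation task applies
its own disjointness filter (new TCRbeta for SPB/TPP-II, new TCRbeta and
new peptide for TPP-III).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import ABSENT, PairRecord

logger = logging.getLogger(__name__)


class SamplingExhaustedError(RuntimeError):
    """Negative sampling could not fill its quota (pathologically dense positives)."""


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of one split/sample realization."""

    train_fraction: float = 0.8
    negative_ratio: int = 5
    peptide_holdout_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")
        if not 0.0 <= self.peptide_holdout_fraction < 1.0:
            raise ValueError("peptide_holdout_fraction must be in [0, 1)")


def split_train_test(records: list[PairRecord], spec: SplitSpec
                     ) -> tuple[list[PairRecord], list[PairRecord]]:
    """Disjoint 80/20-style partition of deduplicated positive records.

    When ``peptide_holdout_fraction`` > 0, that fraction of distinct peptides
    is first assigned wholly to the test side (the mechanism behind
    unseen-peptide evaluation); the remaining records are then partitioned so
    that overall ``|train| = round(train_fraction * n)`` as closely as the
    holdout allows.
    """
    spec.validate()
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))

    held_out_idx: list[int] = []
    pool_idx = list(range(n))
    if spec.peptide_holdout_fraction > 0:
        peptides = sorted({r.peptide for r in records})
        n_held = max(1, int(round(spec.peptide_holdout_fraction * len(peptides))))
        if n_held >= len(peptides):
            raise ValueError("peptide holdout would empty the training side")
        held = set(rng.choice(peptides, size=n_held, replace=False).tolist())
        held_out_idx = [i for i in pool_idx if records[i].peptide in held]
        pool_idx = [i for i in pool_idx if records[i].peptide not in held]

    n_train = int(round(spec.train_fraction * n))
    n_train = min(n_train, len(pool_idx))
    perm = rng.permutation(len(pool_idx))
    train_idx = sorted(pool_idx[i] for i in perm[:n_train])
    test_idx = sorted([pool_idx[i] for i in perm[n_train:]] + held_out_idx)
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def positive_projection(rec: PairRecord) -> tuple:
    """The (TCR side, peptide) identity used for the known-positive check.

    MHC is excluded: binding is defined by the TCR x peptide combination.
    """
    return rec.tcr_side() + (rec.peptide,)


def generate_negatives(positives: list[PairRecord], ratio: int,
                       known_positives: set[tuple], seed: int,
                       max_attempts_factor: int = 100) -> list[PairRecord]:
    """Sample ``ratio * len(positives)`` mismatched non-binding pairs.

    ``known_positives`` is the set of :func:`positive_projection` tuples over
    *all* positive data (train and test), so no sampled negative anywhere is
    secretly a positive.
    """
    n = len(positives)
    if n < 2:
        raise ValueError("need at least 2 positives to mismatch")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    target = ratio * n
    out: list[PairRecord] = []
    attempts = 0
    max_attempts = max_attempts_factor * target
    while len(out) < target:
        if attempts >= max_attempts:
            raise SamplingExhaustedError(
                f"drew {attempts} candidates but produced only {len(out)}/{target} "
                "negatives; positive set too dense for mismatch sampling")
        attempts += 1
        i, j = rng.integers(n), rng.integers(n)
        tcr_donor, pmhc_donor = positives[int(i)], positives[int(j)]
        candidate = PairRecord(
            cdr3_beta=tcr_donor.cdr3_beta, cdr3_alpha=tcr_donor.cdr3_alpha,
            v_beta=tcr_donor.v_beta, j_beta=tcr_donor.j_beta,
            v_alpha=tcr_donor.v_alpha, j_alpha=tcr_donor.j_alpha,
            t_cell_type=tcr_donor.t_cell_type,
            peptide=pmhc_donor.peptide, mhc=pmhc_donor.mhc, label=0)
        if positive_projection(candidate) in known_positives:
            continue
        out.append(candidate)
    return out


# --- feature-dependent sieving -------------------------------------------

def active_fields(config) -> tuple[str, ...]:
    """Record fields that participate in a model's input under ``config``.

    CDR3beta and peptide are always active. Alpha V/J genes are active only
    when both the gene features and the alpha chain are used.
    """
    fields = ["cdr3_beta", "peptide"]
    if config.use_alpha:
        fields.append("cdr3_alpha")
    if config.use_vj:
        fields += ["v_beta", "j_beta"]
        if config.use_alpha:
            fields += ["v_alpha", "j_alpha"]
    if config.use_mhc:
        fields.append("mhc")
    if config.use_t_cell_type:
        fields.append("t_cell_type")
    return tuple(fields)


def _projection(rec: PairRecord, fields: tuple[str, ...]) -> tuple:
    return tuple(getattr(rec, f) for f in fields)


def sieve_test_set(test: list[PairRecord], train: list[PairRecord],
                   config) -> list[PairRecord]:
    """Keep only test records invisible to training under ``config``.

    A test record survives iff its projection onto the active features
    differs from every training record's projection; records the model
    cannot distinguish from a training example are removed.
    """
    fields = active_fields(config)
    train_proj = {_projection(r, fields) for r in train}
    return [r for r in test if _projection(r, fields) not in train_proj]


def filter_by_task(test: list[PairRecord], train: list[PairRecord],
                   task) -> list[PairRecord]:
    """Apply the task-specific disjointness filter after sieving.

    TPP-I: no further filter (only the pairs are new). SPB and TPP-II: keep
    only records with a CDR3beta unseen in training; SPB additionally
    restricts to its fixed target peptide. TPP-III: unseen CDR3beta and
    unseen peptide.
    """
    kind = task.kind
    train_betas = {r.cdr3_beta for r in train}
    train_peps = {r.peptide for r in train}
    if kind == "TPP-I":
        out = list(test)
    elif kind in ("SPB", "TPP-II"):
        out = [r for r in test if r.cdr3_beta not in train_betas]
        if kind == "SPB":
            out = [r for r in out if r.peptide == task.target_peptide]
    elif kind == "TPP-III":
        out = [r for r in test
               if r.cdr3_beta not in train_betas and r.peptide not in train_peps]
    else:
        raise ValueError(f"unknown task kind {kind!r}")
    if not out:
        logger.warning("filter_by_task(%s): empty filtered test set", kind)
    return out


def build_pair_dataset(positives: list[PairRecord], spec: SplitSpec
                       ) -> tuple[list[PairRecord], list[PairRecord]]:
    """Full split -> negative-sample pipeline for one realization.

    Positives are split ``train_fraction``/rest; negatives are sampled
    independently within each side (mismatching that side's positives) at
    ``negative_ratio`` per positive, and are fixed for the whole run rather
    than resampled per epoch.
    """
    train_pos, test_pos = split_train_test(positives, spec)
    known = {positive_projection(r) for r in positives}
    train_neg = generate_negatives(train_pos, spec.negative_ratio, known,
                                   seed=spec.seed * 2 + 1)
    test_neg = generate_negatives(test_pos, spec.negative_ratio, known,
                                  seed=spec.seed * 2 + 2)
    return train_pos + train_neg, test_pos + test_neg
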