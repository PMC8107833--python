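"""AUC computation and the SPB / TPP-I / TPP-II / TPP-III evaluation tasks.

The four tasks answer increasingly strict generalization questions about a
pairing predictor trained on unseen-pair (TPP-I style) data:

* **SPB** -- does an unseen TCR bind one fixed target peptide?
* **TPP-I** -- does a random TCR bind a random peptide, where the pair (but
  not necessarily the TCR or peptide) is new?
* **TPP-II** -- as TPP-I, with TCRbeta sequences unseen in training.
* **TPP-III** -- both the TCRbeta and the peptide are unseen.

AUC is computed as the tie-aware Mann-Whitney statistic: the probability
that a random positive outscores a random negative, ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .records import PairRecord
from .sampling import SplitSpec, build_pair_dataset, filter_by_task, sieve_test_set

TASK_KINDS = ("SPB", "TPP-I", "TPP-II", "TPP-III")


class UndefinedAUCError(ValueError):
    """AUC requested on a single-class label vector."""


@dataclass(frozen=True)
class EvaluationTask:
    kind: str
    target_peptide: str | None = None

    def __post_init__(self):
        if self.kind not in TASK_KINDS:
            raise ValueError(f"unknown task kind {self.kind!r}")
        if (self.kind == "SPB") != (self.target_peptide is not None):
            raise ValueError("target_peptide must be given iff kind is SPB")


@dataclass(frozen=True)
class TaskResult:
    """Outcome of one task on one realization; ``auc`` is NaN when undefined."""

    task: EvaluationTask
    auc: float
    n_pos: int
    n_neg: int
    config: object = None
    realization_seed: int = 0

    @property
    def defined(self) -> bool:
        return not np.isnan(self.auc)


def compute_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Implemented via midranks, which is algebraically identical to the
    all-pairs count for finite samples.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes required to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_task(model, train: list[PairRecord], test: list[PairRecord],
                  task: EvaluationTask, config=None,
                  realization_seed: int = 0) -> TaskResult:
    """Score the sieved test set under one task's disjointness filter.

    ``test`` must already be sieved for the model's feature configuration.
    An empty filtered set or a single surviving class yields an undefined
    result (``auc = NaN``) rather than an exception, so sweeps over many
    configurations and peptides never abort.
    """
    config = config if config is not None else model.config
    filtered = filter_by_task(test, train, task)
    labels = np.array([r.label for r in filtered])
    n_pos = int((labels == 1).sum()) if len(filtered) else 0
    n_neg = int((labels == 0).sum()) if len(filtered) else 0
    if n_pos == 0 or n_neg == 0:
        return TaskResult(task=task, auc=float("nan"), n_pos=n_pos, n_neg=n_neg,
                          config=config, realization_seed=realization_seed)
    scores = model.predict(filtered)
    return TaskResult(task=task, auc=compute_auc(labels, scores),
                      n_pos=n_pos, n_neg=n_neg, config=config,
                      realization_seed=realization_seed)


def run_realizations(positives: list[PairRecord], config, tasks,
                     n_realizations: int = 5, base_seed: int = 0,
                     split_spec: SplitSpec | None = None,
                     train_spec=None, encoder_spec=None) -> list[TaskResult]:
    """Independent split -> sample -> train -> evaluate realizations.

    Each realization derives its own seed from ``base_seed``, draws a fresh
    80/20 split and negative sample, trains a fresh model on the TPP-I-style
    pair data, sieves the test set for ``config``, and evaluates every task
    in ``tasks``. Results carry their realization seed, so distributions and
    percentiles over realizations can be reported downstream.
    """
    from .model import BinderModel, TrainSpec, train as train_model

    if train_spec is None:
        train_spec = TrainSpec()
    tasks = list(tasks)
    need_holdout = any(t.kind == "TPP-III" for t in tasks)
    results: list[TaskResult] = []
    seeds = [int(s) for s in
             np.random.SeedSequence(base_seed).generate_state(n_realizations) >> 1]
    for seed in seeds:
        sspec = split_spec or SplitSpec()
        sspec = SplitSpec(train_fraction=sspec.train_fraction,
                          negative_ratio=sspec.negative_ratio,
                          peptide_holdout_fraction=(
                              sspec.peptide_holdout_fraction if not need_holdout
                              or sspec.peptide_holdout_fraction > 0 else 0.2),
                          seed=seed)
        train_set, test_set = build_pair_dataset(positives, sspec)
        model = BinderModel(config, records=train_set,
                            encoder_spec=encoder_spec, seed=seed)
        tspec = TrainSpec(learning_rate=train_spec.learning_rate,
                          weight_decay=train_spec.weight_decay,
                          batch_train=train_spec.batch_train,
                          batch_val=train_spec.batch_val,
                          pos_weight=train_spec.pos_weight,
                          neg_weight=train_spec.neg_weight,
                          early_stop_patience=train_spec.early_stop_patience,
                          max_epochs=train_spec.max_epochs,
                          strict_decrease=train_spec.strict_decrease,
                          seed=seed)
        train_model(train_set, test_set, model, tspec)
        sieved = sieve_test_set(test_set, train_set, config)
        for task in tasks:
            results.append(evaluate_task(model, train_set, sieved, task,
                                         config=config, realization_seed=seed))
    return results
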