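# tcrpair

Predicting whether a T-cell receptor (TCR) binds a given peptide–MHC (pMHC)
complex is a pairing problem: the model receives two inputs — a receptor and
a presented peptide — and must score their compatibility. `tcrpair` is a
library and command-line toolkit for building, evaluating, and dissecting
such predictors from tabular repertoire data in the style of the curated
McPAS-TCR / VDJdb databases, where each row records the CDR3 sequences of
the β and (often missing) α chain, V/J gene calls, MHC allele, T-cell
compartment (CD4/CD8), and the bound peptide.

It is aimed at computational immunologists who want a controlled,
fully-reproducible sandbox for questions like: *how much does the α chain,
the V/J genes, or the MHC typing add to binding prediction beyond the β-chain
CDR3?* and *how well does a predictor generalize to unseen TCRs or unseen
peptides?*

## The model

Every feature is encoded, the encodings are concatenated, and an MLP emits a
binding probability:

* **CDR3β / CDR3α / peptide** — either an *LSTM acceptor* (residues →
  learned 10-dim embeddings → two stacked LSTM layers of 500 units, dropout
  0.1 between layers; the hidden state at the final residue is the encoding)
  or, for the TCR chains, a pretrained *sequence autoencoder* (one-hot over
  28 positions × 21 symbols → 100-dim latent, fine-tuned during classifier
  training). The peptide always uses the acceptor.
* **Vβ, Jβ, Vα, Jα, MHC** — one learned 50-dim embedding row per distinct
  value (no gene grouping: `TRAV9`, `TRAV9-1`, `TRAV9-3` are three rows;
  `HLA-A*02` ≠ `HLA-A*02:01`), with a reserved *unknown* row shared by
  missing and never-seen values.
* **T-cell type** — a scalar flag (CD4 → 1, CD8 → 0, unknown → 0.5).

Missing α chains are handled architecturally: records with a CDR3α are
scored by **MLP-II** (input includes the α-derived blocks), records without
by **MLP-I** (input excludes them). Each head has one hidden layer of
⌊√(input width)⌋ units (LeakyReLU, dropout 0.1, sigmoid output).

Databases contain only positive pairs, so negatives are manufactured 5:1 by
mismatching: TCR side from one random positive, pMHC side from another,
rejecting known positives. Training minimizes class-weighted binary
cross-entropy (5/6 positives, 1/6 negatives) with Adam, stopping after
three consecutive epochs of decreasing validation AUC.

Evaluation distinguishes four tasks — **SPB** (unseen TCR vs one fixed
peptide), **TPP-I** (unseen pairs), **TPP-II** (unseen TCRβ), **TPP-III**
(unseen TCRβ and peptide) — after *sieving* the test set: any test record
indistinguishable from a training record on the *active* features is
removed, so the measured AUC cannot come from leakage.

Feature contributions are quantified by OLS regression of task AUC on
one-hot configuration indicators (α, V&J as one variable, MHC, T-cell type);
the always-present β chain's contribution is the fitted intercept minus the
0.5 random baseline, and uncertainty is reported as 10/25/75/90 percentiles
over independent realizations.

## Worked example

```python
import tcrpair as tp
from tcrpair.encoders import SequenceEncoderSpec

# 2,000 binding pairs over 5 peptides; 90% of binders carry their
# peptide's 3-mer motif in the CDR3beta
spec = tp.SignalSpec(n_pairs=2000, beta_motif_rate=0.9, seed=7)
positives = tp.generate_repertoire(spec)

train_set, test_set = tp.build_pair_dataset(positives, tp.SplitSpec(seed=7))
config = tp.FeatureConfig()            # beta + peptide only
model = tp.BinderModel(config, records=train_set,
                       encoder_spec=SequenceEncoderSpec(acceptor_units=64),
                       seed=7)
result = tp.train(train_set, test_set, model,
                  tp.TrainSpec(max_epochs=15, learning_rate=1e-3, seed=7))
sieved = tp.sieve_test_set(test_set, train_set, config)
tpp1 = tp.evaluate_task(model, train_set, sieved, tp.EvaluationTask("TPP-I"))
print(f"best epoch {result.best_epoch}, held-out TPP-I AUC {tpp1.auc:.3f}")
```

Output:

```
best epoch 15, held-out TPP-I AUC 0.956
```

i.e. the model recovers the implanted β-motif signal almost perfectly on
2,400 sieved held-out pairs (400 positives, 2,000 sampled negatives). The
same pipeline run on `tp.signal_free_permutation(positives, seed=7)` — the
peptide/MHC columns shuffled against the TCR side — gives AUC 0.530,
confirming that without true association the sieved evaluation sits at the
random baseline.

The same flow is available from the shell:

```bash
tcrpair simulate --seed 7 --n-pairs 2000 --out runs/sim
tcrpair train    --data runs/sim/pairs.csv --seed 7 --out runs/fit
tcrpair evaluate --data runs/sim/pairs.csv --tasks TPP-I,TPP-II,TPP-III \
                 --realizations 5 --out runs/eval
tcrpair contribute --results runs/eval/results.csv --out runs/contrib
```

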