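"""Binder model: dimension contracts, dual-MLP routing, loss arithmetic,
early stopping, and training behavior."""

import math

import numpy as np
import pytest

from conftest import TINY_ACCEPTOR, TINY_AUTOENCODER
from tcrpair.model import (BinderModel, FeatureConfig, TrainSpec,
                           early_stop_epoch, mlp_hidden_width, train,
                           weighted_bce)
from tcrpair.records import PairRecord
from tcrpair.sampling import SplitSpec, build_pair_dataset
from tcrpair.simulate import SignalSpec, generate_repertoire

ALL_CONFIGS = [
    FeatureConfig(use_alpha=a, use_vj=v, use_mhc=m, use_t_cell_type=t,
                  tcr_encoder=enc)
    for a in (False, True) for v in (False, True)
    for m in (False, True) for t in (False, True)
    for enc in ("acceptor", "autoencoder")
]


def _expected_width(config, with_alpha, acceptor_dim=500, ae_dim=100,
                    cat_dim=50, pep_dim=500):
    beta = acceptor_dim if config.tcr_encoder == "acceptor" else ae_dim
    total = beta + pep_dim
    if config.use_alpha and with_alpha:
        total += acceptor_dim if config.tcr_encoder == "acceptor" else ae_dim
    if config.use_vj:
        total += 2 * cat_dim
        if config.use_alpha and with_alpha:
            total += 2 * cat_dim
    if config.use_mhc:
        total += cat_dim
    if config.use_t_cell_type:
        total += 1
    return total


class TestMlpHiddenWidth:
    @pytest.mark.parametrize("n,expected", [(1000, 31), (600, 24), (1, 1),
                                            (1751, 41)])
    def test_floor_sqrt(self, n, expected):
        assert mlp_hidden_width(n) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mlp_hidden_width(0)


class TestDimensionContract:
    """Concatenated width equals the sum of stated component widths for all
    16 feature configurations x 2 encoders, at the default dimensions
    (500-dim acceptor, 100-dim autoencoder latent, 50-dim categoricals,
    1-dim flag, 500-dim peptide)."""

    @pytest.mark.parametrize("config", ALL_CONFIGS,
                             ids=lambda c: f"{c.tcr_encoder}-a{int(c.use_alpha)}"
                                           f"v{int(c.use_vj)}m{int(c.use_mhc)}"
                                           f"t{int(c.use_t_cell_type)}")
    def test_input_width_and_hidden_width(self, config, small_repertoire):
        model = BinderModel(config, records=small_repertoire, seed=0)
        for with_alpha in ({False, True} if config.use_alpha else {False}):
            width = model.input_dim(with_alpha=with_alpha)
            assert width == _expected_width(config, with_alpha)
            head = model.mlp2 if with_alpha else model.mlp1
            assert head.hidden_dim == math.isqrt(width)

    def test_beta_peptide_acceptor_is_1000(self, small_repertoire):
        m = BinderModel(FeatureConfig(), records=small_repertoire, seed=0)
        assert m.input_dim(with_alpha=False) == 1000

    def test_beta_peptide_autoencoder_is_600(self, small_repertoire):
        m = BinderModel(FeatureConfig(tcr_encoder="autoencoder"),
                        records=small_repertoire, seed=0)
        assert m.input_dim(with_alpha=False) == 600

    def test_all_features_acceptor_is_1751(self, small_repertoire):
        cfg = FeatureConfig(use_alpha=True, use_vj=True, use_mhc=True,
                            use_t_cell_type=True)
        m = BinderModel(cfg, records=small_repertoire, seed=0)
        assert m.input_dim(with_alpha=True) == 500 + 500 + 50 * 5 + 1 + 500


class TestWeightedBce:
    def test_single_positive_at_half(self):
        assert weighted_bce([0.5], [1]) == pytest.approx((5 / 6) * np.log(2),
                                                         abs=1e-6)

    def test_single_negative_at_half(self):
        assert weighted_bce([0.5], [0]) == pytest.approx((1 / 6) * np.log(2),
                                                         abs=1e-6)

    def test_perfect_predictions_vanish(self):
        loss = weighted_bce([1 - 1e-9, 1e-9], [1, 0])
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce([0.5], [1, 0])

    def test_matches_logit_form(self, rng):
        """The numpy probability form and the engine's logit form agree."""
        from tcrpair import nn
        z = rng.standard_normal(20)
        y = (rng.random(20) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-z))
        w = np.where(y == 1, 5 / 6, 1 / 6)
        via_logits = float(nn.weighted_bce_logits(nn.constant(z), y, w).data)
        assert weighted_bce(p, y) == pytest.approx(via_logits, abs=1e-10)


class TestEarlyStopping:
    @pytest.mark.parametrize("aucs,stop_epoch", [
        ([0.70, 0.72, 0.71, 0.70, 0.69], 5),   # peak then three decreases
        ([0.70, 0.69, 0.68, 0.67], 4),          # immediate decline
        ([0.70, 0.71, 0.72, 0.73, 0.74], None),  # monotone rise: never stops
        ([0.70, 0.69, 0.68, 0.69, 0.68, 0.67], None),  # runs of 2 reset
        ([0.5, 0.5, 0.5, 0.5], None),           # plateaus are not decreases
    ])
    def test_three_consecutive_decrease_rule(self, aucs, stop_epoch):
        assert early_stop_epoch(aucs, patience=3, strict=True) == stop_epoch

    def test_non_strict_mode_counts_plateaus(self):
        assert early_stop_epoch([0.5, 0.5, 0.5, 0.5], patience=3,
                                strict=False) == 4


@pytest.fixture(scope="module")
def tiny_sets():
    recs = generate_repertoire(SignalSpec(n_pairs=80, alpha_missing_rate=0.4,
                                          seed=42))
    return build_pair_dataset(recs, SplitSpec(seed=42))


class TestRoutingAndPrediction:
    def test_mixed_batch_routing(self, tiny_sets):
        train_set, _ = tiny_sets
        cfg = FeatureConfig(use_alpha=True)
        m = BinderModel(cfg, records=train_set, encoder_spec=TINY_ACCEPTOR, seed=0)
        batch = train_set[:40]
        assert any(r.has_alpha() for r in batch)
        assert any(not r.has_alpha() for r in batch)
        routed = m.batch_logits(batch)
        covered = sorted(i for idx, _ in routed for i in idx)
        assert covered == list(range(len(batch)))
        for idx, _ in routed:
            flags = {batch[i].has_alpha() for i in idx}
            assert len(flags) == 1  # each head sees a pure group

    def test_all_outputs_in_open_unit_interval(self, tiny_sets):
        train_set, _ = tiny_sets
        m = BinderModel(FeatureConfig(use_alpha=True), records=train_set,
                        encoder_spec=TINY_ACCEPTOR, seed=0)
        p = m.predict(train_set[:50])
        assert np.all((p > 0) & (p < 1))

    def test_mlp2_not_instantiated_without_alpha(self, tiny_sets):
        train_set, _ = tiny_sets
        m = BinderModel(FeatureConfig(use_alpha=False), records=train_set,
                        encoder_spec=TINY_ACCEPTOR, seed=0)
        assert m.mlp2 is None

    def test_heads_do_not_share_weights(self, tiny_sets):
        """Scoring an alpha-present record through MLP-II differs from MLP-I's
        score of its alpha-stripped twin (independent heads)."""
        train_set, _ = tiny_sets
        m = BinderModel(FeatureConfig(use_alpha=True), records=train_set,
                        encoder_spec=TINY_ACCEPTOR, seed=0)
        rec = next(r for r in train_set if r.has_alpha())
        from dataclasses import replace
        stripped = replace(rec, cdr3_alpha="", v_alpha="", j_alpha="")
        p_with, p_without = m.predict([rec])[0], m.predict([stripped])[0]
        assert p_with != p_without

    def test_autoencoder_mode_with_alpha(self, tiny_sets):
        train_set, _ = tiny_sets
        cfg = FeatureConfig(use_alpha=True, tcr_encoder="autoencoder")
        m = BinderModel(cfg, records=train_set, encoder_spec=TINY_AUTOENCODER,
                        seed=0)
        p = m.predict(train_set[:20])
        assert p.shape == (20,)


class TestTraining:
    def test_seeded_determinism(self, tiny_sets):
        train_set, test_set = tiny_sets
        logs = []
        for _ in range(2):
            m = BinderModel(FeatureConfig(), records=train_set,
                            encoder_spec=TINY_ACCEPTOR, seed=5)
            r = train(train_set, test_set, m,
                      TrainSpec(max_epochs=2, seed=5, learning_rate=1e-3))
            logs.append([(row["train_loss"], row["val_auc"]) for row in r.log])
        assert logs[0] == logs[1]

    def test_gradient_reaches_autoencoder_params(self, tiny_sets):
        """Fine-tuning contract: one optimizer step changes AE encoder weights."""
        train_set, test_set = tiny_sets
        cfg = FeatureConfig(tcr_encoder="autoencoder")
        m = BinderModel(cfg, records=train_set, encoder_spec=TINY_AUTOENCODER,
                        seed=0)
        before = m.beta_encoder.params["beta_ae.enc_W1"].data.copy()
        train(train_set[:128], test_set, m,
              TrainSpec(max_epochs=1, seed=0, learning_rate=1e-3))
        after = m.beta_encoder.params["beta_ae.enc_W1"].data
        assert not np.array_equal(before, after)

    def test_single_class_validation_rejected(self, tiny_sets):
        train_set, _ = tiny_sets
        m = BinderModel(FeatureConfig(), records=train_set,
                        encoder_spec=TINY_ACCEPTOR, seed=0)
        only_pos = [r for r in train_set if r.label == 1][:10]
        with pytest.raises(ValueError, match="both classes"):
            train(train_set, only_pos, m, TrainSpec(max_epochs=1, seed=0))

    def test_learns_separable_motif_signal(self):
        """On ~200 strongly motif-marked pairs, validation AUC reaches 0.95
        within 30 epochs."""
        recs = generate_repertoire(SignalSpec(
            n_pairs=200, beta_motif_rate=1.0, peptides=("GILGFVFTL", "NLVPMVATV"),
            alpha_missing_rate=1.0, seed=77))
        train_set, test_set = build_pair_dataset(recs, SplitSpec(seed=77))
        m = BinderModel(FeatureConfig(), records=train_set,
                        encoder_spec=TINY_ACCEPTOR, seed=77)
        r = train(train_set, test_set, m,
                  TrainSpec(max_epochs=30, seed=77, learning_rate=3e-3))
        assert r.best_val_auc >= 0.95
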