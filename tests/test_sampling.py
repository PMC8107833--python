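"""Splitting, negative sampling, sieving, and task filtering."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from tcrpair.evaluation import EvaluationTask
from tcrpair.model import FeatureConfig
from tcrpair.records import PairRecord
from tcrpair.sampling import (SamplingExhaustedError, SplitSpec,
                              build_pair_dataset, filter_by_task,
                              generate_negatives, positive_projection,
                              sieve_test_set, split_train_test)
from tcrpair.simulate import SignalSpec, generate_repertoire


class TestSplitTrainTest:
    def test_eighty_twenty_counts(self):
        recs = generate_repertoire(SignalSpec(n_pairs=10, seed=0))
        train, test = split_train_test(recs, SplitSpec(seed=0))
        assert len(train) == 8 and len(test) == 2

    def test_partition_is_exact(self, small_repertoire):
        train, test = split_train_test(small_repertoire, SplitSpec(seed=3))
        combined = sorted(train + test, key=repr)
        assert combined == sorted(small_repertoire, key=repr)
        assert not (set(train) & set(test))

    def test_seed_reproducibility(self, small_repertoire):
        a = split_train_test(small_repertoire, SplitSpec(seed=7))
        b = split_train_test(small_repertoire, SplitSpec(seed=7))
        assert a == b

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([PairRecord("CASSF", "AAA")], SplitSpec())

    def test_peptide_holdout_keeps_peptides_out_of_train(self, small_repertoire):
        spec = SplitSpec(peptide_holdout_fraction=0.2, seed=5)
        train, test = split_train_test(small_repertoire, spec)
        held = {r.peptide for r in test} - {r.peptide for r in train}
        assert held, "at least one peptide should be wholly held out"


class TestGenerateNegatives:
    def test_exact_ratio(self, small_repertoire):
        known = {positive_projection(r) for r in small_repertoire}
        negs = generate_negatives(small_repertoire[:10], 5, known, seed=1)
        assert len(negs) == 50
        assert all(n.label == 0 for n in negs)

    def test_composition_from_two_donors(self, small_repertoire):
        positives = small_repertoire[:30]
        known = {positive_projection(r) for r in positives}
        tcr_sides = {r.tcr_side() for r in positives}
        pmhc_sides = {r.pmhc_side() for r in positives}
        for n in generate_negatives(positives, 5, known, seed=2):
            assert n.tcr_side() in tcr_sides
            assert n.pmhc_side() in pmhc_sides

    def test_no_negative_is_a_known_positive(self, small_repertoire):
        known = {positive_projection(r) for r in small_repertoire}
        for n in generate_negatives(small_repertoire, 5, known, seed=3):
            assert positive_projection(n) not in known

    def test_reproducible(self, small_repertoire):
        known = {positive_projection(r) for r in small_repertoire}
        a = generate_negatives(small_repertoire, 2, known, seed=9)
        b = generate_negatives(small_repertoire, 2, known, seed=9)
        assert a == b

    def test_exhaustion_when_no_valid_negative_exists(self):
        # two positives sharing one TCR and one peptide: every mismatch is positive
        positives = [
            PairRecord("CASSF", "GILGFVFTL", mhc="HLA-A*02"),
            PairRecord("CASSF", "GILGFVFTL", mhc="HLA-B*07"),
        ]
        known = {positive_projection(r) for r in positives}
        with pytest.raises(SamplingExhaustedError):
            generate_negatives(positives, 5, known, seed=0,
                               max_attempts_factor=10)

    def test_build_pair_dataset_ratio_holds_in_both_sides(self, small_repertoire):
        train, test = build_pair_dataset(small_repertoire, SplitSpec(seed=4))
        for side in (train, test):
            n_pos = sum(r.label == 1 for r in side)
            n_neg = sum(r.label == 0 for r in side)
            assert n_neg == 5 * n_pos


def _cfg(**kw):
    return FeatureConfig(**kw)


class TestSieveTestSet:
    def test_collision_on_inactive_feature_removes_record(self):
        train = [PairRecord("CASSX", "GILGFVFTL")]
        test = [PairRecord("CASSX", "GILGFVFTL", cdr3_alpha="CAVRDF")]
        assert sieve_test_set(test, train, _cfg(use_alpha=False)) == []

    def test_distinct_on_active_feature_is_retained(self):
        train = [PairRecord("CASSX", "GILGFVFTL", cdr3_alpha="CAVAAF")]
        test = [PairRecord("CASSX", "GILGFVFTL", cdr3_alpha="CAVRDF")]
        assert sieve_test_set(test, train, _cfg(use_alpha=True)) == test

    def test_new_beta_retained_under_every_config(self):
        train = [PairRecord("CASSX", "GILGFVFTL")]
        test = [PairRecord("CASSY", "GILGFVFTL")]
        for use_alpha in (False, True):
            for use_vj in (False, True):
                cfg = _cfg(use_alpha=use_alpha, use_vj=use_vj)
                assert sieve_test_set(test, train, cfg) == test

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sieve_monotonicity(self, seed):
        """Records removed under a finer identity (more active features) are a
        subset of those removed under a coarser one."""
        recs = generate_repertoire(SignalSpec(
            n_pairs=60, peptides=("AAA", "CCC"), alpha_missing_rate=0.3,
            seed=seed % 9973))
        train, test = recs[:40], recs[40:]
        coarse = _cfg()
        fine = _cfg(use_alpha=True, use_vj=True, use_mhc=True,
                    use_t_cell_type=True)
        removed_coarse = set(test) - set(sieve_test_set(test, train, coarse))
        removed_fine = set(test) - set(sieve_test_set(test, train, fine))
        assert removed_fine <= removed_coarse


class TestFilterByTask:
    def _fixture(self):
        train = [PairRecord("CASSX", "GILGFVFTL"), PairRecord("CASSZ", "NLVPMVATV")]
        test = [
            PairRecord("CASSX", "NLVPMVATV"),   # seen beta, seen peptide, new pair
            PairRecord("CASSY", "GILGFVFTL"),   # new beta, seen peptide
            PairRecord("CASSW", "LLWNGPMAV"),   # new beta, new peptide
        ]
        return train, test

    def test_tpp1_keeps_everything(self):
        train, test = self._fixture()
        assert filter_by_task(test, train, EvaluationTask("TPP-I")) == test

    def test_tpp2_requires_new_beta(self):
        train, test = self._fixture()
        out = filter_by_task(test, train, EvaluationTask("TPP-II"))
        assert out == test[1:]

    def test_tpp3_requires_new_beta_and_new_peptide(self):
        train, test = self._fixture()
        out = filter_by_task(test, train, EvaluationTask("TPP-III"))
        assert out == [test[2]]

    def test_spb_restricts_to_target_peptide(self):
        train, test = self._fixture()
        out = filter_by_task(test, train,
                             EvaluationTask("SPB", target_peptide="GILGFVFTL"))
        assert out == [test[1]]

    def test_empty_result_is_empty_list_not_error(self):
        train, test = self._fixture()
        out = filter_by_task(test, train,
                             EvaluationTask("SPB", target_peptide="SSYRRPVGI"))
        assert out == []

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_subset_chain_tpp3_tpp2_sieved(self, seed):
        recs = generate_repertoire(SignalSpec(n_pairs=80, seed=seed % 9973))
        train, test = recs[:60], recs[60:]
        sieved = sieve_test_set(test, train, _cfg())
        t2 = filter_by_task(sieved, train, EvaluationTask("TPP-II"))
        t3 = filter_by_task(sieved, train, EvaluationTask("TPP-III"))
        assert set(t3) <= set(t2) <= set(sieved)
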