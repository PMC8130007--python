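"""Workflow engine: initialization sizes, round mechanics, pool accounting."""

from __future__ import annotations

import numpy as np
import pytest

from altriage import (
    ALVariant,
    ClassifierSpec,
    InitialSizes,
    SamplingConfig,
    SplitRatios,
    combined_retrieve,
    initialize,
    run_active_learning,
    run_round,
    synthetic_oracle,
)
from altriage.al_engine import fit_models
from altriage.corpus_io import Label

VARIANT_FLAGS = {
    ALVariant.TRADITIONAL: (False, False, False),
    ALVariant.TRADITIONAL_PLUS_RANDOM: (True, False, False),
    ALVariant.DUAL_MODEL: (True, True, False),
    ALVariant.DUAL_MODEL_VAL_UPDATE: (True, True, True),
}


@pytest.mark.parametrize("variant,flags", VARIANT_FLAGS.items())
def test_variant_flags(variant, flags):
    assert (
        variant.uses_random_negatives,
        variant.dual_models,
        variant.updates_validation,
    ) == flags


class TestInitialize:
    def test_reference_first_round_sizes_dual(self, midi_corpus):
        """With the default draw sizes the dual workflow starts from
        1,200 / 400 training documents and a 600-document validation set."""
        corpus, _ = midi_corpus
        state = initialize(ALVariant.DUAL_MODEL, corpus, seed=3)
        assert len(state.train_ml1.all_ids()) == 1200  # 200 pos + 1000 random
        assert len(state.train_ml2.all_ids()) == 400  # 200 pos + 200 neg
        assert len(state.validation.all_ids()) == 600  # 200 + 200 + 200
        # dual training sets share their positive stratum
        assert state.train_ml1.pos == state.train_ml2.pos

    def test_reference_first_round_sizes_traditional(self, midi_corpus):
        corpus, _ = midi_corpus
        state = initialize(ALVariant.TRADITIONAL, corpus, seed=3)
        assert state.train_ml1 is None
        assert len(state.train_ml2.all_ids()) == 400
        assert len(state.validation.all_ids()) == 400
        assert state.validation.rand == []  # no random-negative stratum

    def test_same_seed_identical(self, midi_corpus):
        corpus, _ = midi_corpus
        a = initialize(ALVariant.DUAL_MODEL_VAL_UPDATE, corpus, seed=11)
        b = initialize(ALVariant.DUAL_MODEL_VAL_UPDATE, corpus, seed=11)
        assert a.train_ml1.all_ids() == b.train_ml1.all_ids()
        assert a.validation.all_ids() == b.validation.all_ids()
        assert a.unlabeled_pool == b.unlabeled_pool

    def test_insufficient_stratum_named(self, small_corpus, midi_corpus):
        corpus, _ = small_corpus
        with pytest.raises(ValueError, match="positive"):
            initialize(ALVariant.DUAL_MODEL, corpus, sizes=InitialSizes(), seed=0)
        corpus, _ = midi_corpus
        with pytest.raises(ValueError, match="random"):
            initialize(
                ALVariant.DUAL_MODEL, corpus,
                sizes=InitialSizes(train_random=5000), seed=0,
            )

    def test_disjoint_pools(self, midi_corpus):
        corpus, _ = midi_corpus
        for variant in ALVariant:
            initialize(variant, corpus, seed=5).assert_disjoint()


class TestRunRound:
    def test_two_round_invariants(self, small_corpus, small_fs, small_sizes):
        corpus, truth = small_corpus
        oracle = synthetic_oracle(truth)
        state = initialize(
            ALVariant.DUAL_MODEL_VAL_UPDATE, corpus, sizes=small_sizes, seed=1
        )
        val_before = len(state.validation.all_ids())
        pool_before = len(state.unlabeled_pool)
        new = run_round(
            state,
            ALVariant.DUAL_MODEL_VAL_UPDATE,
            small_fs,
            SamplingConfig(seed=1),
            oracle,
            classifier_spec=ClassifierSpec(),
            seed=1,
        )
        new.assert_disjoint()
        n_acq = len(new.acquisitions)
        assert n_acq > 0
        assert new.round == state.round + 1
        # pool shrinkage equals acquisitions; oracle effort equals the log
        assert pool_before - len(new.unlabeled_pool) == n_acq
        assert oracle.query_count == n_acq
        # validation grew by (about) its ratio share of the batch
        expected_val = round(SplitRatios().to_validation * n_acq)
        grown = len(new.validation.all_ids()) - val_before
        assert abs(grown - expected_val) <= 1

    def test_noop_round_changes_only_counter(self, small_corpus, small_fs, small_sizes):
        corpus, truth = small_corpus
        oracle = synthetic_oracle(truth)
        # a sliver of a band plus an unreachable mining threshold: no acquisitions
        cfg = SamplingConfig(band_low=0.49999, band_high=0.5, high_conf_threshold=1.0)
        state = initialize(ALVariant.DUAL_MODEL, corpus, sizes=small_sizes, seed=2)
        new = run_round(
            state, ALVariant.DUAL_MODEL, small_fs, cfg, oracle,
            classifier_spec=ClassifierSpec(), seed=2,
        )
        if new.acquisitions:  # the sliver caught something; nothing to assert
            pytest.skip("band sliver was not empty for this corpus")
        assert new.round == state.round + 1
        assert new.train_ml1.all_ids() == state.train_ml1.all_ids()
        assert new.train_ml2.all_ids() == state.train_ml2.all_ids()
        assert new.validation.all_ids() == state.validation.all_ids()
        assert new.unlabeled_pool == state.unlabeled_pool
        # refit on unchanged data reproduces identical probabilities
        X = small_fs.rows(new.unlabeled_pool[:20])
        old_models = fit_models(
            state, ALVariant.DUAL_MODEL, small_fs, ClassifierSpec(), seed=2
        )
        for name in ("ml1", "ml2"):
            assert (
                new.models[name].predict_proba(X) == old_models[name].predict_proba(X)
            ).all()

    def test_acquired_positives_grow_training_positives(self, small_corpus, small_fs, small_sizes):
        """With hidden positives in the random pool, mining grows the
        positive training stratum between rounds (the reference tables'
        200+ -> 217+ pattern)."""
        corpus, truth = small_corpus
        oracle = synthetic_oracle(truth)
        state = initialize(
            ALVariant.TRADITIONAL_PLUS_RANDOM, corpus, sizes=small_sizes, seed=3
        )
        pos_before = len(state.train_ml1.pos)
        new = run_round(
            state, ALVariant.TRADITIONAL_PLUS_RANDOM, small_fs,
            SamplingConfig(seed=3), oracle, classifier_spec=ClassifierSpec(), seed=3,
        )
        found_pos = [r for r in new.acquisitions if r.oracle_label is Label.POSITIVE]
        assert len(new.train_ml1.pos) == pos_before + len(found_pos)
        assert len(found_pos) > 0


class TestCombinedRetrieve:
    def test_and_rule_and_intersection(self, small_fs, small_corpus, small_sizes):
        corpus, truth = small_corpus
        state = initialize(ALVariant.DUAL_MODEL, corpus, sizes=small_sizes, seed=4)
        models = fit_models(
            state, ALVariant.DUAL_MODEL, small_fs, ClassifierSpec(), seed=4
        )
        X = small_fs.rows(state.unlabeled_pool[:50])
        decision = combined_retrieve(models["ml1"], models["ml2"], X, threshold=0.5)
        p1 = models["ml1"].predict_proba(X)
        p2 = models["ml2"].predict_proba(X)
        assert (decision == ((p1 >= 0.5) & (p2 >= 0.5))).all()
        assert combined_retrieve(models["ml1"], models["ml2"], X, threshold=0.0).all()

    def test_feature_space_mismatch_rejected(self, small_fs, small_corpus, small_sizes):
        corpus, _ = small_corpus
        state = initialize(ALVariant.DUAL_MODEL, corpus, sizes=small_sizes, seed=4)
        models = fit_models(
            state, ALVariant.DUAL_MODEL, small_fs, ClassifierSpec(), seed=4
        )
        import dataclasses

        other = dataclasses.replace(models["ml2"], feature_terms=("a", "b"))
        with pytest.raises(ValueError):
            combined_retrieve(models["ml1"], other, small_fs.rows(state.unlabeled_pool[:5]))


class TestRunActiveLearning:
    def test_full_run_reproducible_and_accounted(self, small_corpus, small_features, small_sizes):
        corpus, truth = small_corpus
        kwargs = dict(
            variant=ALVariant.DUAL_MODEL_VAL_UPDATE,
            classifier_spec=ClassifierSpec(),
            sizes=small_sizes,
            sampling_cfg=SamplingConfig(),
            rounds=2,
            seed=9,
            features=small_features,
        )
        r1 = run_active_learning(corpus, synthetic_oracle(truth), **kwargs)
        r2 = run_active_learning(corpus, synthetic_oracle(truth), **kwargs)
        assert r1.metrics.equals(r2.metrics)
        assert len(r1.rounds) == 2
        # evaluation rows: 2 rounds x 2 models
        assert len(r1.metrics) == 4
        assert (r1.metrics["p_at_r"].dropna() <= 1).all()

    def test_single_model_variants_have_one_model(self, small_corpus, small_features, small_sizes):
        corpus, truth = small_corpus
        for variant, model_name in (
            (ALVariant.TRADITIONAL, "ml2"),
            (ALVariant.TRADITIONAL_PLUS_RANDOM, "ml1"),
        ):
            res = run_active_learning(
                corpus, synthetic_oracle(truth), variant,
                sizes=small_sizes, rounds=2, seed=9, features=small_features,
            )
            assert set(res.metrics["model"]) == {model_name}
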