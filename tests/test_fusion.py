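import numpy as np
import pytest

import respfusion as rf
from respfusion.fusion import (
    FusionArchitectureSpec,
    build_model,
    majority_vote,
    predict,
    train,
    train_hybrid,
)
from respfusion.types import MODEL_CHANNEL_ORDER, PipelineConfig


def subset_snippets(snips, labels=None):
    return snips


class TestArchitecture:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_branch_counts_per_strategy(self, k):
        signals = MODEL_CHANNEL_ORDER[:k]
        early = build_model(FusionArchitectureSpec("early", signals))
        slate = build_model(FusionArchitectureSpec("signal_late", signals))
        senlate = build_model(FusionArchitectureSpec("sensor_late", signals))
        assert early.n_branches == 1
        assert slate.n_branches == k
        assert senlate.n_branches == 2 * k

    def test_parameter_count_closed_form(self):
        # early over 4 channels: conv 4 filters x (4 ch x 20) + 4 biases;
        # conv output 182 -> pool 4 -> 45 per filter -> dense 180 + bias
        m = build_model(FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER))
        conv = 4 * (4 * 20) + 4
        dense = 4 * 45 + 1
        assert m.n_params == conv + dense
        # signal-late: 4 branches of conv 4 x (1 x 20) + 4; dense 4*180 + 1
        m2 = build_model(FusionArchitectureSpec("signal_late", MODEL_CHANNEL_ORDER))
        assert m2.n_params == 4 * (4 * 20 + 4) + (4 * 4 * 45 + 1)

    def test_hybrid_not_buildable_directly(self):
        with pytest.raises(rf.RespFusionError, match="train_hybrid"):
            build_model(FusionArchitectureSpec("hybrid", MODEL_CHANNEL_ORDER))

    def test_empty_signals_rejected(self):
        with pytest.raises(rf.RespFusionError):
            FusionArchitectureSpec("early", ())

    def test_unknown_strategy_rejected(self):
        with pytest.raises(rf.RespFusionError):
            FusionArchitectureSpec("mid_fusion", MODEL_CHANNEL_ORDER)


class TestTraining:
    def test_deterministic_given_seed(self, toy_snippets):
        cfg = PipelineConfig(epochs=3, seed=9)
        outs = []
        for _ in range(2):
            m = build_model(FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER, seed=9))
            train(m, toy_snippets, cfg)
            outs.append(predict(m, toy_snippets).scores)
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-7)

    def test_loss_decreases_on_separable_toy(self, toy_snippets):
        cfg = PipelineConfig(epochs=8, seed=2, dropout=0.0)
        m = build_model(
            FusionArchitectureSpec("signal_late", MODEL_CHANNEL_ORDER, dropout=0.0, seed=2)
        )
        _, history = train(m, toy_snippets, cfg)
        assert history.loss[-1] < history.loss[0]

    def test_overfits_training_set(self, toy_snippets):
        from respfusion.evaluation import evaluate_predictions

        cfg = PipelineConfig(epochs=15, seed=4, dropout=0.0)
        m = build_model(
            FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER, dropout=0.0, seed=4)
        )
        train(m, toy_snippets, cfg)
        pv = predict(m, toy_snippets)
        perf = evaluate_predictions(pv.y, toy_snippets.labels)
        assert perf.p > 90

    def test_single_class_rejected(self, toy_snippets):
        import dataclasses

        degenerate = dataclasses.replace(
            toy_snippets, labels=np.zeros(len(toy_snippets), dtype=np.int64)
        )
        m = build_model(FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER))
        with pytest.raises(rf.RespFusionError, match="both classes"):
            train(m, degenerate, PipelineConfig(epochs=1))

    def test_channel_order_mismatch_rejected(self, toy_snippets):
        import dataclasses

        m = build_model(FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER))
        train(m, toy_snippets, PipelineConfig(epochs=1))
        shuffled = dataclasses.replace(
            toy_snippets, channel_names=tuple(reversed(toy_snippets.channel_names))
        )
        with pytest.raises(rf.RespFusionError, match="channel order"):
            predict(m, shuffled)


class TestPrediction:
    def test_scores_in_unit_interval_and_thresholded(self, toy_snippets):
        m = build_model(FusionArchitectureSpec("signal_late", MODEL_CHANNEL_ORDER, seed=1))
        train(m, toy_snippets, PipelineConfig(epochs=2, seed=1))
        pv = predict(m, toy_snippets)
        assert np.all((pv.scores >= 0) & (pv.scores <= 1))
        np.testing.assert_array_equal(pv.y, (pv.scores >= 0.5).astype(int))

    def test_duplicated_snippet_identical_score(self, toy_snippets):
        import dataclasses

        m = build_model(FusionArchitectureSpec("early", MODEL_CHANNEL_ORDER, seed=3))
        train(m, toy_snippets, PipelineConfig(epochs=2, seed=3))
        dup = dataclasses.replace(
            toy_snippets,
            data=np.concatenate([toy_snippets.data[:1], toy_snippets.data[:1]]),
            starts=np.zeros(2, dtype=np.int64),
            subject_ids=np.full(2, "toy", dtype=object),
            scenarios=np.full(2, "city", dtype=object),
            labels=toy_snippets.labels[:2],
        )
        pv = predict(m, dup)
        assert pv.scores[0] == pv.scores[1]


class TestMajorityVote:
    def test_exhaustive_truth_table(self):
        import itertools

        for a, b, c in itertools.product([0, 1], repeat=3):
            out = majority_vote(np.array([a]), np.array([b]), np.array([c]))
            assert out[0] == int(a + b + c >= 2)

    def test_all_equal_vectors_identity(self, rng):
        v = rng.integers(0, 2, size=50)
        np.testing.assert_array_equal(majority_vote(v, v, v), v)

    def test_length_mismatch(self):
        with pytest.raises(rf.RespFusionError):
            majority_vote(np.array([1]), np.array([1, 0]), np.array([0]))

    def test_non_binary_rejected(self):
        with pytest.raises(rf.RespFusionError):
            majority_vote(np.array([2]), np.array([0]), np.array([1]))


class TestHybrid:
    def test_vote_equals_member_majority(self, toy_snippets):
        cfg = PipelineConfig(epochs=2, seed=5)
        ensemble = train_hybrid(toy_snippets, cfg, seed=5)
        assert set(ensemble.members) == {"early", "signal_late", "sensor_late"}
        votes = {k: predict(m, toy_snippets).y for k, m in ensemble.members.items()}
        expected = majority_vote(
            votes["early"], votes["signal_late"], votes["sensor_late"]
        )
        np.testing.assert_array_equal(ensemble.predict(toy_snippets).y, expected)

    def test_reproducible_run_to_run(self, toy_snippets):
        cfg = PipelineConfig(epochs=2, seed=8)
        y1 = train_hybrid(toy_snippets, cfg, seed=8).predict(toy_snippets).y
        y2 = train_hybrid(toy_snippets, cfg, seed=8).predict(toy_snippets).y
        np.testing.assert_array_equal(y1, y2)
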