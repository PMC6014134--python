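"""Training loop, ensembling, evaluation, persistence."""

import numpy as np
import pytest

from chemrel.corpus import CLASSES, GoldRelation, Prediction
from chemrel.evaluate import micro_prf, micro_prf_relations
from chemrel.model import (
    Hyperparams,
    SPINNModel,
    TreeLSTMModel,
    ensemble_predict,
    fit_ensemble,
    load_results,
    predictions_from_labels,
)


class TestMicroPRF:
    def test_hand_counted_three_instances(self):
        rep = micro_prf(["CPR:3", "CPR:4", "False"],
                        ["CPR:3", "False", "CPR:4"])
        assert (rep.total_tp, rep.total_fp, rep.total_fn) == (1, 1, 1)
        assert rep.micro_precision == pytest.approx(50.0)
        assert rep.micro_recall == pytest.approx(50.0)
        assert rep.micro_f1 == pytest.approx(50.0)

    def test_perfect_predictions(self):
        gold = ["CPR:5", "False", "CPR:9"]
        rep = micro_prf(gold, gold)
        assert rep.micro_f1 == pytest.approx(100.0)

    def test_all_false_predictions_zero_recall(self):
        rep = micro_prf(["CPR:3", "CPR:4"], ["False", "False"])
        assert rep.micro_recall == 0.0
        assert rep.micro_f1 == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            micro_prf(["CPR:3"], ["CPR:11"])

    def test_matches_bruteforce_pooled_contingency(self):
        """Pooled counts equal a direct per-class recount on 200 random
        label vectors."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            gold = [CLASSES[i] for i in rng.integers(0, 6, n)]
            pred = [CLASSES[i] for i in rng.integers(0, 6, n)]
            rep = micro_prf(gold, pred)
            tp = sum(1 for g, p in zip(gold, pred) if g == p != "False")
            fp = sum(1 for g, p in zip(gold, pred) if p != "False" and g != p)
            fn = sum(1 for g, p in zip(gold, pred) if g != "False" and g != p)
            assert (rep.total_tp, rep.total_fp, rep.total_fn) == (tp, fp, fn)

    def test_relation_file_scoring(self):
        gold = [GoldRelation("1", "CPR:4", "T1", "T2"),
                GoldRelation("2", "CPR:3", "T1", "T2")]
        preds = [Prediction("1", "CPR:4", "T1", "T2", 1.0),
                 Prediction("2", "CPR:5", "T1", "T2", 1.0)]
        rep = micro_prf_relations(gold, preds)
        assert (rep.total_tp, rep.total_fp, rep.total_fn) == (1, 1, 1)


class TestTraining:
    def test_zero_learning_rate_leaves_params_unchanged(self, prepared):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=2,
                         learning_rate=0.0)
        model = TreeLSTMModel(instances[:10], trees[:10], table, vocab, hp)
        res = model.fit(seed=0)
        fresh = model._init_params(0)
        for key, t in fresh["cell"].tensors().items():
            assert np.array_equal(t.value, res.bundle["cell"].tensors()[key].value)

    def test_same_seed_identical_history(self, prepared):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=3)
        m = TreeLSTMModel(instances[:12], trees[:12], table, vocab, hp)
        r1 = m.fit(seed=5)
        r2 = m.fit(seed=5)
        assert r1.loss_history == r2.loss_history

    def test_loss_decreases_over_first_steps(self, prepared):
        """Adam on 20 instances: final loss below initial loss after 50
        optimizer steps (batch 4 -> 5 steps/epoch, 10 epochs)."""
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=8, batch_size=4, epochs=10)
        m = TreeLSTMModel(instances[:20], trees[:20], table, vocab, hp)
        res = m.fit(seed=1)
        assert res.loss_history[-1] < res.loss_history[0]

    def test_empty_training_set_rejected(self, prepared):
        _, _, table, vocab = prepared
        with pytest.raises(ValueError):
            TreeLSTMModel([], [], table, vocab).fit(seed=0)

    def test_misaligned_tree_rejected(self, prepared):
        instances, trees, table, vocab = prepared
        with pytest.raises(ValueError, match="leaves"):
            TreeLSTMModel(instances[:2], [trees[1], trees[0]], table, vocab)

    def test_spinn_trains_and_history_is_finite(self, prepared):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=2)
        m = SPINNModel(instances[:10], trees[:10], table, vocab, hp)
        res = m.fit(seed=2)
        assert len(res.loss_history) == 2
        assert all(np.isfinite(v) for v in res.loss_history)

    def test_summary_mentions_model_and_counts(self, prepared):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=1)
        res = TreeLSTMModel(instances[:8], trees[:8], table, vocab, hp).fit(seed=0)
        text = res.summary()
        assert "Tree-LSTM" in text
        assert "micro_f" in text


class TestEnsemble:
    @pytest.fixture()
    def two_members(self, prepared):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=2)
        model = TreeLSTMModel(instances[:10], trees[:10], table, vocab, hp)
        return model, fit_ensemble(model, k=2, base_seed=3)

    def test_k1_is_identity(self, two_members):
        model, members = two_members
        labels, scores = ensemble_predict(members[:1])
        assert labels == members[0].predict()
        assert np.allclose(scores, members[0].predict_logits())

    def test_identical_members_reproduce_single(self, two_members):
        model, members = two_members
        solo = members[0]
        labels, _ = ensemble_predict([solo, solo, solo])
        assert labels == solo.predict()

    def test_logit_sum_is_elementwise(self, two_members):
        _, members = two_members
        _, scores = ensemble_predict(members)
        expected = members[0].predict_logits() + members[1].predict_logits()
        assert np.allclose(scores, expected)

    def test_dominating_member_wins(self, two_members):
        """If one member's logits dwarf the others, the sum's argmax is that
        member's argmax (linearity of the summation rule)."""
        _, members = two_members
        boosted = members[0].predict_logits()
        dominated_scores = boosted * 1000 + members[1].predict_logits()
        assert ([CLASSES[i] for i in dominated_scores.argmax(1)]
                == members[0].predict())

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([])

    def test_hand_summed_logits(self):
        """Members with logits [2,0,...] and [0,1,...] sum to [2,1,...] and
        predict class 0."""
        a = np.zeros((1, 6)); a[0, 0] = 2.0
        b = np.zeros((1, 6)); b[0, 1] = 1.0
        total = a + b
        assert total[0, 0] == 2.0 and total[0, 1] == 1.0
        assert CLASSES[int(total.argmax(1)[0])] == "False"


class TestPersistence:
    def test_checkpoint_roundtrip(self, prepared, tmp_path):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=2)
        model = TreeLSTMModel(instances[:10], trees[:10], table, vocab, hp)
        res = model.fit(seed=4)
        path = tmp_path / "ckpt.npz"
        res.save(path)
        back = load_results(path, model)
        assert back.predict() == res.predict()
        assert np.allclose(back.predict_logits(), res.predict_logits())

    def test_model_type_mismatch_rejected(self, prepared, tmp_path):
        instances, trees, table, vocab = prepared
        hp = Hyperparams(hidden_size=4, batch_size=8, epochs=1)
        res = TreeLSTMModel(instances[:6], trees[:6], table, vocab, hp).fit(seed=0)
        path = tmp_path / "ckpt.npz"
        res.save(path)
        spinn = SPINNModel(instances[:6], trees[:6], table, vocab, hp)
        with pytest.raises(ValueError, match="treelstm"):
            load_results(path, spinn)


class TestPredictionDedup:
    def test_false_instances_emit_nothing(self, prepared):
        instances, *_ = prepared
        preds = predictions_from_labels(instances[:3], ["False"] * 3)
        assert preds == []

    def test_duplicate_pair_keeps_best_score(self, prepared):
        instances, *_ = prepared
        inst = instances[0]
        scores = np.array([[1.0, 0, 0, 0, 0, 0], [5.0, 0, 0, 0, 0, 0]])
        preds = predictions_from_labels([inst, inst], ["CPR:3", "CPR:3"], scores)
        assert len(preds) == 1
        assert preds[0].score == 5.0
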