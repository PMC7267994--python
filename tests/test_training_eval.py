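import numpy as np
import pytest

import oracles
from cpigcn.model import ModelConfig
from cpigcn.preprocessing import SplitSpec, resplit
from cpigcn.training_eval import (
    EvalCounts,
    TrainSpec,
    evaluate,
    examples_to_gold,
    micro_f,
    predict,
    predictions_to_tuples,
    sweep,
    train,
)
from test_model import make_ex, tiny_model

GROUPS = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")


def random_tuples(rng, n):
    return {
        (f"D{rng.integers(5)}", f"T{rng.integers(8)}", f"T{rng.integers(8)}",
         GROUPS[rng.integers(5)])
        for _ in range(n)
    }


class TestMicroF:
    def test_perfect_predictions(self):
        gold = {("D1", "T1", "T2", "CPR:4"), ("D2", "T1", "T3", "CPR:6")}
        counts = micro_f(gold, gold)
        assert counts.precision == counts.recall == counts.f_score == 100.0

    def test_hand_case(self):
        # TP=2, FP=1, FN=3
        gold = {(f"D{i}", "T1", "T2", "CPR:4") for i in range(5)}
        pred = {("D0", "T1", "T2", "CPR:4"), ("D1", "T1", "T2", "CPR:4"),
                ("D9", "T1", "T2", "CPR:4")}
        counts = micro_f(gold, pred)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 3)
        assert counts.precision == pytest.approx(66.67, abs=0.005)
        assert counts.recall == pytest.approx(40.0)
        assert counts.f_score == pytest.approx(50.0)

    def test_empty_predictions_zero_rule(self):
        gold = {("D1", "T1", "T2", "CPR:4")}
        counts = micro_f(gold, set())
        assert counts.precision == counts.recall == counts.f_score == 0.0
        assert micro_f(set(), set()).f_score == 0.0

    def test_non_evaluated_class_rejected(self):
        with pytest.raises(ValueError, match="non-evaluated"):
            micro_f({("D1", "T1", "T2", "CPR:1")}, set())
        with pytest.raises(ValueError, match="non-evaluated"):
            micro_f(set(), {("D1", "T1", "T2", "NEG")})

    def test_matches_naive_oracle_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            gold = random_tuples(rng, int(rng.integers(0, 25)))
            pred = random_tuples(rng, int(rng.integers(0, 25)))
            p, r, f, tp, fp, fn = oracles.oracle_micro_f(gold, pred)
            counts = micro_f(gold, pred)
            assert (counts.tp, counts.fp, counts.fn) == (tp, fp, fn)
            assert counts.precision == pytest.approx(p)
            assert counts.recall == pytest.approx(r)
            assert counts.f_score == pytest.approx(f)

    def test_adding_correct_prediction_never_decreases_f(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            gold = random_tuples(rng, int(rng.integers(1, 20)))
            pred = random_tuples(rng, int(rng.integers(0, 20)))
            missing = list(gold - pred)
            if not missing:
                continue
            before = micro_f(gold, pred).f_score
            after = micro_f(gold, pred | {missing[0]}).f_score
            assert after >= before

    def test_per_class_counts_sum_to_pooled(self):
        rng = np.random.default_rng(29)
        gold = random_tuples(rng, 20)
        pred = random_tuples(rng, 20)
        counts = micro_f(gold, pred)
        assert sum(c[0] for c in counts.per_class.values()) == counts.tp
        assert sum(c[1] for c in counts.per_class.values()) == counts.fp
        assert sum(c[2] for c in counts.per_class.values()) == counts.fn

    def test_f_consistency_invariant(self):
        counts = EvalCounts(tp=3, fp=2, fn=4)
        p, r = counts.precision, counts.recall
        assert counts.f_score == pytest.approx(2 * p * r / (p + r))


def separable_examples(n, seed=0):
    """Trigger word fully determines the label; trivially learnable."""
    rng = np.random.default_rng(seed)
    triggers = {"CPR:3": "activates", "CPR:4": "inhibits", "CPR:5": "agonizes",
                "CPR:6": "antagonizes", "CPR:9": "metabolizes", "NEG": "sees"}
    labels = sorted(triggers)
    out = []
    for i in range(n):
        label = labels[int(rng.integers(len(labels)))]
        tokens = [f"CHEM{rng.integers(30)}", triggers[label], f"PROT{rng.integers(30)}", "."]
        ex = make_ex(tokens, [2, 0, 2, 2], {1}, {3}, label)
        ex.doc_id = f"D{i % 25}"
        ex.sent_index = i
        ex.chem_id = f"T{2 * i}"
        ex.prot_id = f"T{2 * i + 1}"
        out.append(ex)
    return out


SMALL_CFG = dict(word_dim=12, pos_dim=3, etype_dim=3, lstm_hidden=12, gcn_hidden=12,
                 gcn_layers=2, prune_distance=2, dropout=0.0)


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        examples = separable_examples(200, seed=1)
        train_ex, dev_ex = resplit(examples, SplitSpec(seed=0))
        # Full-batch descent: epoch losses are deterministic and must fall.
        spec = TrainSpec(max_epochs=3, patience=10, batch_size=len(train_ex), seed=0)
        result = train(train_ex, dev_ex, ModelConfig(**SMALL_CFG), spec)
        losses = [h["train_loss"] for h in result.history]
        assert losses[0] > losses[1] > losses[2]

    def test_same_seed_identical_history(self):
        examples = separable_examples(60, seed=2)
        train_ex, dev_ex = examples[:50], examples[50:]
        spec = TrainSpec(max_epochs=2, batch_size=8, seed=7)
        a = train(train_ex, dev_ex, ModelConfig(**SMALL_CFG), spec)
        b = train(train_ex, dev_ex, ModelConfig(**SMALL_CFG), spec)
        assert a.history == b.history

    def test_patience_one_stops_after_two_evaluations(self):
        examples = separable_examples(40, seed=3)
        # Constant dev F (empty-ish model improvement unlikely in 1 epoch with
        # lr 0): freeze learning so dev F never improves after epoch 1.
        spec = TrainSpec(max_epochs=10, patience=1, batch_size=8, seed=0, learning_rate=1e-9)
        result = train(examples[:30], examples[30:], ModelConfig(**SMALL_CFG), spec)
        assert len(result.history) == 2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], ModelConfig(**SMALL_CFG), TrainSpec())


class TestPredict:
    def test_all_neg_argmax_gives_no_records(self):
        m = tiny_model()
        m.params["out_W"].data[:] = 0.0
        m.params["out_b"].data[:] = 0.0
        m.params["out_b"].data[0] = 10.0  # negative class dominates
        examples = separable_examples(10)
        assert predict(examples, m) == []

    def test_prediction_count_bounded(self):
        m = tiny_model()
        examples = separable_examples(20)
        assert len(predict(examples, m)) <= 20

    def test_empty_examples(self):
        assert predict([], tiny_model()) == []


class TestSweep:
    def test_two_pruning_variants_two_rows(self):
        examples = separable_examples(40, seed=4)
        variants = [("N=0", ModelConfig(**{**SMALL_CFG, "prune_distance": 0})),
                    ("N=2", ModelConfig(**SMALL_CFG))]
        rows = sweep(variants, examples[:30], examples[30:], TrainSpec(max_epochs=1, batch_size=8))
        assert [r.variant for r in rows] == ["N=0", "N=2"]

    def test_feature_grid_four_rows(self):
        examples = separable_examples(40, seed=5)
        grid = [
            ("word", ModelConfig(**{**SMALL_CFG, "use_pos": False, "use_etype": False})),
            ("word+pos", ModelConfig(**{**SMALL_CFG, "use_etype": False})),
            ("word+etype", ModelConfig(**{**SMALL_CFG, "use_pos": False})),
            ("word+pos+etype", ModelConfig(**SMALL_CFG)),
        ]
        rows = sweep(grid, examples[:30], examples[30:], TrainSpec(max_epochs=1, batch_size=8))
        assert len(rows) == 4

    def test_deterministic_rows(self):
        examples = separable_examples(30, seed=6)
        variants = [("base", ModelConfig(**SMALL_CFG))]
        spec = TrainSpec(max_epochs=1, batch_size=8, seed=3)
        a = sweep(variants, examples[:20], examples[20:], spec)
        b = sweep(variants, examples[:20], examples[20:], spec)
        assert a == b


class TestGoldExtraction:
    def test_examples_to_gold_skips_negatives(self):
        examples = separable_examples(50, seed=7)
        gold = examples_to_gold(examples)
        assert all(t[3] != "NEG" for t in gold)
        assert len(gold) == sum(1 for ex in examples if ex.label != "NEG")
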