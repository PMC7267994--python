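"""Training loop, prediction, micro-averaged P/R/F evaluation, and sweeps.

Optimization is plain stochastic gradient descent (the tuned learning rate
of 0.3 presupposes SGD) with global gradient-norm clipping at 5.  Model
selection is early stopping on development-set micro-F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from cpigcn.corpus_io import EVALUATED_GROUPS, NEGATIVE_LABEL, Prediction
from cpigcn.model import CLASS_LABELS, ModelConfig, RelationModel
from cpigcn.preprocessing import SentenceExample
from cpigcn.vocab import Vocab

logger = logging.getLogger(__name__)

RelationTuple = tuple[str, str, str, str]  # (doc_id, arg1_id, arg2_id, class)


@dataclass(frozen=True)
class TrainSpec:
    learning_rate: float = 0.3
    max_epochs: int = 30
    patience: int = 5
    batch_size: int = 32
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EvalCounts:
    """Pooled and per-class confusion counts with micro P/R/F percentages."""

    tp: int
    fp: int
    fn: int
    per_class: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def micro_f(gold: Iterable[RelationTuple], predicted: Iterable[RelationTuple]) -> EvalCounts:
    """Micro-averaged precision/recall/F over the five evaluated classes.

    ``TP = |gold ∩ predicted|`` and so on by set arithmetic; each of P, R and
    F is defined as 0 when its denominator vanishes.  Duplicates count once.
    """
    gold_set = set(gold)
    pred_set = set(predicted)
    for t in gold_set | pred_set:
        if t[3] not in EVALUATED_GROUPS:
            raise ValueError(f"relation tuple with non-evaluated class: {t}")
    per_class: dict[str, tuple[int, int, int]] = {}
    for cls in sorted(EVALUATED_GROUPS):
        g = {t for t in gold_set if t[3] == cls}
        p = {t for t in pred_set if t[3] == cls}
        per_class[cls] = (len(g & p), len(p - g), len(g - p))
    return EvalCounts(
        tp=len(gold_set & pred_set),
        fp=len(pred_set - gold_set),
        fn=len(gold_set - pred_set),
        per_class=per_class,
    )


def examples_to_gold(examples: Sequence[SentenceExample]) -> set[RelationTuple]:
    """Gold relation tuples carried by a list of labeled examples."""
    return {
        (ex.doc_id, ex.chem_id, ex.prot_id, ex.label)
        for ex in examples
        if ex.label != NEGATIVE_LABEL
    }


def predict(examples: Sequence[SentenceExample], model: RelationModel, batch_size: int = 64) -> list[Prediction]:
    """Argmax predictions; negatives emit no relation record; argmax ties
    resolve to the lowest class index."""
    if not examples:
        return []
    probs = model.predict_proba(list(examples), batch_size=batch_size)
    out: list[Prediction] = []
    for ex, row in zip(examples, probs):
        label = CLASS_LABELS[int(np.argmax(row))]
        if label != NEGATIVE_LABEL:
            out.append(Prediction(ex.doc_id, label, ex.chem_id, ex.prot_id))
    return out


def predictions_to_tuples(predictions: Iterable[Prediction]) -> set[RelationTuple]:
    return {p.as_tuple() for p in predictions}


def evaluate(examples: Sequence[SentenceExample], model: RelationModel) -> EvalCounts:
    gold = examples_to_gold(examples)
    preds = predictions_to_tuples(predict(examples, model))
    return micro_f(gold, preds)


@dataclass
class TrainResult:
    model: RelationModel
    history: list[dict]
    best_epoch: int
    best_dev_f: float


def build_vocabs(examples: Sequence[SentenceExample]) -> tuple[Vocab, Vocab, Vocab]:
    words = Vocab.from_sequences(ex.tokens for ex in examples)
    pos = Vocab.from_sequences(ex.pos_tags for ex in examples)
    etype = Vocab.from_sequences(ex.entity_tags for ex in examples)
    return words, pos, etype


def _sgd_step(model: RelationModel, lr: float, clip_norm: float) -> None:
    grads = [(p, p.grad) for p in model.params.values() if p.grad is not None]
    total = np.sqrt(sum(float((g * g).sum()) for _, g in grads))
    scale = clip_norm / total if clip_norm > 0 and total > clip_norm else 1.0
    for p, g in grads:
        p.data -= lr * scale * g
    model.zero_grad()


def train(
    train_examples: Sequence[SentenceExample],
    dev_examples: Sequence[SentenceExample],
    config: ModelConfig,
    spec: TrainSpec,
    pretrained_vectors: dict[str, np.ndarray] | None = None,
) -> TrainResult:
    """SGD training with per-epoch dev micro-F logging and early stopping.

    Returns the parameters achieving the best dev micro-F.  Fully
    reproducible for a given spec seed.
    """
    if not train_examples:
        raise ValueError("empty training set")
    word_vocab, pos_vocab, etype_vocab = build_vocabs(train_examples)
    model = RelationModel(
        config, word_vocab, pos_vocab, etype_vocab, seed=spec.seed,
        pretrained_vectors=pretrained_vectors,
    )
    rng = np.random.default_rng(spec.seed + 1)
    history: list[dict] = []
    best_state = model.state_dict()
    best_f, best_epoch, wait = -1.0, 0, 0
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(train_examples))
        losses = []
        for lo in range(0, len(order), spec.batch_size):
            batch_examples = [train_examples[i] for i in order[lo : lo + spec.batch_size]]
            batch = model.make_batch(batch_examples)
            loss, _ = model.loss(batch, training=True)
            loss.backward()
            _sgd_step(model, spec.learning_rate, spec.clip_norm)
            losses.append(float(loss.data))
        dev_f = evaluate(dev_examples, model).f_score if dev_examples else 0.0
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "dev_f": dev_f})
        logger.info("epoch %d: train loss %.4f, dev micro-F %.2f", epoch, history[-1]["train_loss"], dev_f)
        if dev_f > best_f:
            best_f, best_epoch, wait = dev_f, epoch, 0
            best_state = model.state_dict()
        else:
            wait += 1
            if wait >= spec.patience:
                break
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_epoch=best_epoch, best_dev_f=best_f)


@dataclass
class SweepRow:
    variant: str
    precision: float
    recall: float
    f_score: float
    seed: int


def sweep(
    variants: Sequence[tuple[str, ModelConfig]],
    train_examples: Sequence[SentenceExample],
    dev_examples: Sequence[SentenceExample],
    spec: TrainSpec,
) -> list[SweepRow]:
    """Train and evaluate one model per configuration variant.

    Each variant gets its own deterministic seed derived from the base seed
    and its position, so identical grids reproduce identical tables.
    """
    rows: list[SweepRow] = []
    for i, (name, config) in enumerate(variants):
        variant_spec = replace(spec, seed=spec.seed + 1000 * i)
        result = train(train_examples, dev_examples, config, variant_spec)
        counts = evaluate(dev_examples, result.model)
        rows.append(SweepRow(name, counts.precision, counts.recall, counts.f_score, variant_spec.seed))
        logger.info("variant %s: P %.2f R %.2f F %.2f", name, counts.precision, counts.recall, counts.f_score)
    return rows
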