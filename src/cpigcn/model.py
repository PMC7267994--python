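"""The neural scoring function.

Per-token input vectors are the concatenation of word, POS and entity-type
embeddings.  A bidirectional LSTM contextualizes the whole sentence; an
L-layer graph convolutional network then propagates information along the
pruned dependency graph, where each layer computes

    h_i = relu( (sum_j A~_ij · W h_j) / d_i + b )

with ``A~`` the self-looped pruned adjacency and ``d_i`` its row degree.
Max-pooling over the kept tokens and over each entity span yields the
sentence and entity representations, which a one-hidden-layer FFNN and a
linear softmax layer turn into class probabilities.

Both encoder stages are ablatable: with ``use_gcn=False`` the model is a
plain Bi-LSTM classifier; with ``use_bilstm=False`` the GCN consumes the raw
embeddings.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cpigcn import autograd as ag
from cpigcn.autograd import Tensor
from cpigcn.depgraph import DependencyTree, build_adjacency, prune
from cpigcn.preprocessing import SentenceExample
from cpigcn.vocab import Vocab, build_embedding_matrix

#: Fixed class order; index 0 is the negative class, ties in argmax resolve
#: to the lowest index.
CLASS_LABELS = ("NEG", "CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")
LABEL_TO_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


@dataclass
class ModelConfig:
    """Every hyperparameter of the scorer, defaulting to the tuned values."""

    word_dim: int = 200
    pos_dim: int = 20
    etype_dim: int = 60
    lstm_hidden: int = 200
    gcn_hidden: int = 200
    gcn_layers: int = 2
    prune_distance: float = 2  # N; math.inf keeps the whole LCA subtree
    dropout: float = 0.5
    n_classes: int = 6
    ffnn_hidden: int | None = None  # defaults to gcn_hidden
    use_pos: bool = True
    use_etype: bool = True
    use_bilstm: bool = True
    use_gcn: bool = True
    pool_whole_sentence: bool = False  # pool h_sent over all tokens, not kept

    def __post_init__(self) -> None:
        for name in ("word_dim", "pos_dim", "etype_dim", "lstm_hidden", "gcn_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if self.n_classes != len(CLASS_LABELS):
            raise ValueError(f"n_classes must be {len(CLASS_LABELS)}")
        if not self.use_bilstm and not self.use_gcn:
            raise ValueError("at least one of use_bilstm/use_gcn must be enabled")

    @property
    def input_dim(self) -> int:
        dim = self.word_dim
        if self.use_pos:
            dim += self.pos_dim
        if self.use_etype:
            dim += self.etype_dim
        return dim

    @property
    def encoder_dim(self) -> int:
        """Dimensionality of per-token vectors entering the pooling stage."""
        lstm_out = 2 * self.lstm_hidden if self.use_bilstm else self.input_dim
        return self.gcn_hidden if self.use_gcn else lstm_out

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["prune_distance"] == math.inf:
            d["prune_distance"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("prune_distance") == "inf":
            d["prune_distance"] = math.inf
        return cls(**d)


@dataclass
class Batch:
    """Dense, padded arrays for a list of examples."""

    word_idx: np.ndarray  # (B, T) int
    pos_idx: np.ndarray  # (B, T) int
    etype_idx: np.ndarray  # (B, T) int
    token_mask: np.ndarray  # (B, T) bool, true on real tokens
    adj_norm: np.ndarray  # (B, T, T) float, rows of A~ divided by degree
    sent_mask: np.ndarray  # (B, T) bool, pooling set for h_sent
    chem_mask: np.ndarray  # (B, T) bool
    prot_mask: np.ndarray  # (B, T) bool
    labels: np.ndarray  # (B,) int

    @property
    def size(self) -> int:
        return self.word_idx.shape[0]


def _span_mask(span: Sequence[int], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for i in span:
        mask[i - 1] = True
    return mask


class RelationModel:
    """Parameter bundle plus forward pass; trained by an external loop."""

    def __init__(
        self,
        config: ModelConfig,
        word_vocab: Vocab,
        pos_vocab: Vocab,
        etype_vocab: Vocab,
        seed: int = 0,
        pretrained_vectors: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.word_vocab = word_vocab
        self.pos_vocab = pos_vocab
        self.etype_vocab = etype_vocab
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(pretrained_vectors)

    # -- parameters ---------------------------------------------------------

    def _param(self, name: str, shape: tuple[int, ...], scale: float | None = None) -> Tensor:
        if scale is None:
            scale = 1.0 / math.sqrt(shape[0])
        tensor = Tensor(self.rng.uniform(-scale, scale, size=shape), requires_grad=True)
        self.params[name] = tensor
        return tensor

    def _init_params(self, pretrained: dict[str, np.ndarray] | None) -> None:
        cfg = self.config
        word_table = build_embedding_matrix(self.word_vocab, cfg.word_dim, self.rng, pretrained)
        self.params["emb_word"] = Tensor(word_table, requires_grad=True)
        self._param("emb_pos", (len(self.pos_vocab), cfg.pos_dim), scale=0.25)
        self._param("emb_etype", (len(self.etype_vocab), cfg.etype_dim), scale=0.25)
        if cfg.use_bilstm:
            for direction in ("fw", "bw"):
                self._param(f"lstm_{direction}_Wx", (cfg.input_dim, 4 * cfg.lstm_hidden))
                self._param(f"lstm_{direction}_Wh", (cfg.lstm_hidden, 4 * cfg.lstm_hidden))
                bias = np.zeros(4 * cfg.lstm_hidden)
                bias[cfg.lstm_hidden : 2 * cfg.lstm_hidden] = 1.0  # forget-gate bias
                self.params[f"lstm_{direction}_b"] = Tensor(bias, requires_grad=True)
        gcn_in = 2 * cfg.lstm_hidden if cfg.use_bilstm else cfg.input_dim
        if cfg.use_gcn:
            for layer in range(cfg.gcn_layers):
                in_dim = gcn_in if layer == 0 else cfg.gcn_hidden
                self._param(f"gcn_W{layer}", (in_dim, cfg.gcn_hidden))
                self.params[f"gcn_b{layer}"] = Tensor(np.zeros(cfg.gcn_hidden), requires_grad=True)
        rep = cfg.encoder_dim
        hidden = cfg.ffnn_hidden or cfg.gcn_hidden
        self._param("ffnn_W", (3 * rep, hidden))
        self.params["ffnn_b"] = Tensor(np.zeros(hidden), requires_grad=True)
        self._param("out_W", (hidden, cfg.n_classes))
        self.params["out_b"] = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params or self.params[k].data.shape != v.shape:
                raise ValueError(f"parameter {k!r} missing or shape-mismatched")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- batching -----------------------------------------------------------

    def make_batch(self, examples: Sequence[SentenceExample]) -> Batch:
        cfg = self.config
        B = len(examples)
        T = max(len(ex.tokens) for ex in examples)
        word_idx = np.zeros((B, T), dtype=np.int64)
        pos_idx = np.zeros((B, T), dtype=np.int64)
        etype_idx = np.zeros((B, T), dtype=np.int64)
        token_mask = np.zeros((B, T), dtype=bool)
        adj_norm = np.zeros((B, T, T), dtype=np.float64)
        sent_mask = np.zeros((B, T), dtype=bool)
        chem_mask = np.zeros((B, T), dtype=bool)
        prot_mask = np.zeros((B, T), dtype=bool)
        labels = np.zeros(B, dtype=np.int64)
        for b, ex in enumerate(examples):
            n = len(ex.tokens)
            word_idx[b, :n] = [self.word_vocab[w] for w in ex.tokens]
            pos_idx[b, :n] = [self.pos_vocab[p] for p in ex.pos_tags]
            etype_idx[b, :n] = [self.etype_vocab[t] for t in ex.entity_tags]
            token_mask[b, :n] = True
            tree = DependencyTree(ex.heads)
            if cfg.use_gcn:
                kept = prune(tree, ex.chem_span, ex.prot_span, cfg.prune_distance)
            else:
                kept = frozenset(range(1, n + 1))
            graph = build_adjacency(tree, kept, n=T)
            adj_norm[b] = graph.A_tilde / graph.d[:, None]
            if cfg.use_gcn and not cfg.pool_whole_sentence:
                sent_mask[b] = _span_mask(sorted(kept), T)
            else:
                sent_mask[b, :n] = True
            chem_mask[b] = _span_mask(sorted(ex.chem_span), T)
            prot_mask[b] = _span_mask(sorted(ex.prot_span), T)
            labels[b] = LABEL_TO_INDEX[ex.label]
        return Batch(word_idx, pos_idx, etype_idx, token_mask, adj_norm,
                     sent_mask, chem_mask, prot_mask, labels)

    # -- forward ------------------------------------------------------------

    def embed(self, batch: Batch, training: bool = False) -> Tensor:
        """Per-token input vectors x_i = [word_i; pos_i; etype_i]."""
        cfg = self.config
        parts = [ag.embedding(self.params["emb_word"], batch.word_idx)]
        if cfg.use_pos:
            parts.append(ag.embedding(self.params["emb_pos"], batch.pos_idx))
        if cfg.use_etype:
            parts.append(ag.embedding(self.params["emb_etype"], batch.etype_idx))
        X = parts[0] if len(parts) == 1 else ag.concat(parts, axis=-1)
        return ag.dropout(X, cfg.dropout, self.rng, training)

    def _lstm_direction(self, X: Tensor, token_mask: np.ndarray, direction: str) -> list[Tensor]:
        cfg = self.config
        H = cfg.lstm_hidden
        B, T = token_mask.shape
        Wx = self.params[f"lstm_{direction}_Wx"]
        Wh = self.params[f"lstm_{direction}_Wh"]
        b = self.params[f"lstm_{direction}_b"]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(T) if direction == "fw" else range(T - 1, -1, -1)
        outputs: list[Tensor | None] = [None] * T
        for t in order:
            x_t = ag.timestep(X, t)
            gates = x_t @ Wx + h @ Wh + b
            i = ag.sigmoid(ag.narrow(gates, 0, H))
            f = ag.sigmoid(ag.narrow(gates, H, H))
            g = ag.tanh(ag.narrow(gates, 2 * H, H))
            o = ag.sigmoid(ag.narrow(gates, 3 * H, H))
            c_new = f * c + i * g
            h_new = o * ag.tanh(c_new)
            # Padded positions carry the previous state through unchanged, so
            # batched computation matches per-sentence computation exactly.
            m = Tensor(token_mask[:, t : t + 1].astype(np.float64))
            one_minus = Tensor(1.0 - token_mask[:, t : t + 1].astype(np.float64))
            h = h_new * m + h * one_minus
            c = c_new * m + c * one_minus
            outputs[t] = h
        return outputs  # type: ignore[return-value]

    def encode_bilstm(self, X: Tensor, token_mask: np.ndarray) -> Tensor:
        """Contextualized tokens h_i = [forward_i; backward_i], (B, T, 2H)."""
        fw = self._lstm_direction(X, token_mask, "fw")
        bw = self._lstm_direction(X, token_mask, "bw")
        per_token = [ag.concat([f, b], axis=-1) for f, b in zip(fw, bw)]
        return ag.stack(per_token, axis=1)

    def gcn_forward(self, H: Tensor, adj_norm: np.ndarray, training: bool = False) -> Tensor:
        """L degree-normalized graph convolutions with self-loops."""
        cfg = self.config
        A = Tensor(adj_norm)
        out = H
        for layer in range(cfg.gcn_layers):
            if layer > 0:
                out = ag.dropout(out, cfg.dropout, self.rng, training)
            W = self.params[f"gcn_W{layer}"]
            b = self.params[f"gcn_b{layer}"]
            out = ag.relu(A @ (out @ W) + b)
        return out

    def pool_and_classify(self, H: Tensor, batch: Batch) -> Tensor:
        """h_sent/h_c/h_p max-pooling, FFNN, and the output linear layer."""
        h_sent = ag.masked_max(H, batch.sent_mask)
        h_c = ag.masked_max(H, batch.chem_mask)
        h_p = ag.masked_max(H, batch.prot_mask)
        rep = ag.concat([h_sent, h_c, h_p], axis=-1)
        h_final = ag.relu(rep @ self.params["ffnn_W"] + self.params["ffnn_b"])
        return h_final @ self.params["out_W"] + self.params["out_b"]

    def forward(self, batch: Batch, training: bool = False) -> Tensor:
        """Logits (B, n_classes) for a batch."""
        X = self.embed(batch, training)
        H = self.encode_bilstm(X, batch.token_mask) if self.config.use_bilstm else X
        if self.config.use_gcn:
            H = self.gcn_forward(H, batch.adj_norm, training)
        return self.pool_and_classify(H, batch)

    def loss(self, batch: Batch, training: bool = True) -> tuple[Tensor, np.ndarray]:
        logits = self.forward(batch, training)
        return ag.softmax_cross_entropy(logits, batch.labels)

    def predict_proba(self, examples: Sequence[SentenceExample], batch_size: int = 32) -> np.ndarray:
        """Class probabilities, (n_examples, n_classes)."""
        chunks = []
        for lo in range(0, len(examples), batch_size):
            batch = self.make_batch(examples[lo : lo + batch_size])
            logits = self.forward(batch, training=False)
            chunks.append(ag.softmax(logits.data))
        return np.concatenate(chunks, axis=0) if chunks else np.zeros((0, self.config.n_classes))

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint with the full configuration and vocabularies embedded."""
        meta = {
            "config": self.config.to_dict(),
            "word_vocab": self.word_vocab.to_list(),
            "pos_vocab": self.pos_vocab.to_list(),
            "etype_vocab": self.etype_vocab.to_list(),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "RelationModel":
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        model = cls(
            ModelConfig.from_dict(meta["config"]),
            Vocab.from_list(meta["word_vocab"]),
            Vocab.from_list(meta["pos_vocab"]),
            Vocab.from_list(meta["etype_vocab"]),
        )
        model.load_state_dict(state)
        return model
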