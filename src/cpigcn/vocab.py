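"""Token/POS/entity-tag vocabularies and pretrained word-vector loading."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

PAD = "<pad>"
UNK = "<unk>"


class Vocab:
    """String-to-index mapping with reserved padding (0) and unknown (1) rows."""

    def __init__(self, tokens: Iterable[str] = ()):
        self.itos: list[str] = [PAD, UNK]
        self.stoi: dict[str, int] = {PAD: 0, UNK: 1}
        for tok in tokens:
            self.add(tok)

    def add(self, token: str) -> int:
        if token not in self.stoi:
            self.stoi[token] = len(self.itos)
            self.itos.append(token)
        return self.stoi[token]

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, token: str) -> bool:
        return token in self.stoi

    def __getitem__(self, token: str) -> int:
        return self.stoi.get(token, 1)

    def __iter__(self) -> Iterator[str]:
        return iter(self.itos)

    @classmethod
    def from_sequences(cls, sequences: Iterable[Iterable[str]]) -> "Vocab":
        vocab = cls()
        for seq in sequences:
            for tok in seq:
                vocab.add(tok)
        return vocab

    def to_list(self) -> list[str]:
        return list(self.itos)

    @classmethod
    def from_list(cls, itos: list[str]) -> "Vocab":
        if itos[:2] != [PAD, UNK]:
            raise ValueError("vocabulary list must start with the pad and unk symbols")
        vocab = cls()
        for tok in itos[2:]:
            vocab.add(tok)
        return vocab


def load_word_vectors(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Load word vectors in word2vec/FastText text format.

    The optional first line may be a ``<count> <dim>`` header.  Returns the
    mapping and the vector dimensionality.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if lineno == 1 and len(parts) == 2:
                continue  # header
            if len(parts) < 2:
                continue
            word, values = parts[0], parts[1:]
            vec = np.asarray([float(v) for v in values], dtype=np.float64)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(f"{path}:{lineno}: inconsistent vector dimension")
            vectors[word] = vec
    if dim is None:
        raise ValueError(f"{path}: no vectors found")
    return vectors, dim


def build_embedding_matrix(
    vocab: Vocab,
    dim: int,
    rng: np.random.Generator,
    pretrained: dict[str, np.ndarray] | None = None,
    scale: float = 0.25,
) -> np.ndarray:
    """Initial embedding table: pretrained rows where available, otherwise
    uniform in ``[-scale, scale]``; the padding row stays zero."""
    table = rng.uniform(-scale, scale, size=(len(vocab), dim))
    table[0] = 0.0
    if pretrained:
        for i, tok in enumerate(vocab.itos):
            if i >= 2 and tok in pretrained:
                vec = pretrained[tok]
                if vec.size != dim:
                    raise ValueError(
                        f"pretrained dimension {vec.size} does not match configured {dim}"
                    )
                table[i] = vec
    return table
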