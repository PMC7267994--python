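"""From corpus records to sentence-level classified candidate examples.

The pipeline is: sentence splitting, candidate-pair generation (one example
per chemical/gene mention pair co-occurring in a sentence), dependency-parse
attachment from CoNLL-U, digit normalization, entity-type tagging, and a
document-level 9:1 train/dev re-split.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from cpigcn.conllu_io import ConlluSentence, read_conllu
from cpigcn.corpus_io import (
    Corpus,
    Document,
    EntityMention,
    EVALUATED_GROUPS,
    NEGATIVE_LABEL,
)

SentenceRange = tuple[int, int]
Splitter = Callable[[str], list[SentenceRange]]

CHEM_TAG = "chemical"
GENE_TAG = "gen"
OUTSIDE_TAG = "O"


class AlignmentError(ValueError):
    """A CoNLL-U parse could not be aligned with a candidate sentence."""


@dataclass
class SentenceExample:
    """One candidate chemical-protein pair in one sentence.

    Token indices are 1-based; ``heads[i-1] == 0`` marks the root.  Before
    :func:`attach_parses` runs, ``tokens`` is a provisional whitespace
    tokenization and ``heads`` a provisional flat tree.
    """

    doc_id: str
    sent_index: int
    text: str
    sent_start: int  # character offset of the sentence in the document text
    tokens: list[str]
    pos_tags: list[str]
    entity_tags: list[str]
    heads: list[int]
    chem_span: frozenset[int]
    prot_span: frozenset[int]
    chem_id: str
    prot_id: str
    chem_char: tuple[int, int]  # document-level character offsets
    prot_char: tuple[int, int]
    label: str = NEGATIVE_LABEL

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        if n < 1:
            raise ValueError(f"{self.key()}: empty token sequence")
        if not (len(self.pos_tags) == len(self.entity_tags) == len(self.heads) == n):
            raise ValueError(f"{self.key()}: sequence length mismatch")
        for span, name in ((self.chem_span, "chem_span"), (self.prot_span, "prot_span")):
            if not span or not all(1 <= i <= n for i in span):
                raise ValueError(f"{self.key()}: invalid {name} {sorted(span)}")
        if sum(1 for h in self.heads if h == 0) != 1:
            raise ValueError(f"{self.key()}: head array must have exactly one root")
        if self.label != NEGATIVE_LABEL and self.label not in EVALUATED_GROUPS:
            raise ValueError(f"{self.key()}: bad label {self.label!r}")

    def key(self) -> str:
        return f"{self.doc_id}/s{self.sent_index}/{self.chem_id}-{self.prot_id}"

    @property
    def n(self) -> int:
        return len(self.tokens)

    def to_json(self) -> str:
        d = {
            "doc_id": self.doc_id,
            "sent_index": self.sent_index,
            "text": self.text,
            "sent_start": self.sent_start,
            "tokens": self.tokens,
            "pos_tags": self.pos_tags,
            "entity_tags": self.entity_tags,
            "heads": self.heads,
            "chem_span": sorted(self.chem_span),
            "prot_span": sorted(self.prot_span),
            "chem_id": self.chem_id,
            "prot_id": self.prot_id,
            "chem_char": list(self.chem_char),
            "prot_char": list(self.prot_char),
            "label": self.label,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, line: str) -> "SentenceExample":
        d = json.loads(line)
        d["chem_span"] = frozenset(d["chem_span"])
        d["prot_span"] = frozenset(d["prot_span"])
        d["chem_char"] = tuple(d["chem_char"])
        d["prot_char"] = tuple(d["prot_char"])
        return cls(**d)


@dataclass(frozen=True)
class SplitSpec:
    seed: int
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class CandidateStats:
    """Counters emitted by candidate generation."""

    n_candidates: int = 0
    n_cross_sentence_relations: int = 0
    n_dropped_overlap: int = 0
    n_boundary_mentions_repaired: int = 0


_SENTENCE_BREAK = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")


def default_splitter(text: str) -> list[SentenceRange]:
    """Regex sentence splitter: break after ``.!?`` followed by whitespace and
    an upper-case/numeral sentence opener."""
    ranges: list[SentenceRange] = []
    start = 0
    for match in _SENTENCE_BREAK.finditer(text):
        ranges.append((start, match.start()))
        start = match.end()
    if start < len(text):
        ranges.append((start, len(text)))
    return ranges or [(0, len(text))]


def split_sentences(
    document: Document,
    mentions: Sequence[EntityMention] = (),
    *,
    separator: str = "\t",
    splitter: Splitter | None = None,
    stats: CandidateStats | None = None,
) -> list[tuple[str, SentenceRange]]:
    """Split a document into sentences over ``document.text(separator)``.

    The title is always its own sentence.  Boundaries that would cut an
    entity mention in two are repaired by merging the adjacent sentences, so
    every mention lies in exactly one sentence.
    """
    splitter = splitter or default_splitter
    text = document.text(separator)
    title_len = len(document.title)
    ranges: list[SentenceRange] = [(0, title_len)]
    offset = title_len + len(separator)
    for lo, hi in splitter(document.abstract):
        ranges.append((lo + offset, hi + offset))
    # Repair: merge adjacent ranges while a mention crosses a boundary.
    changed = True
    while changed:
        changed = False
        for i in range(len(ranges) - 1):
            boundary = ranges[i][1]
            nxt_start = ranges[i + 1][0]
            # A mention crosses the boundary if it starts before the first
            # range ends and finishes after the second range starts.
            if any(m.start < boundary and m.end > nxt_start for m in mentions):
                ranges[i : i + 2] = [(ranges[i][0], ranges[i + 1][1])]
                if stats is not None:
                    stats.n_boundary_mentions_repaired += 1
                changed = True
                break
    return [(text[lo:hi], (lo, hi)) for lo, hi in ranges]


def _whitespace_tokens(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def _project_span(char_start: int, char_end: int, offsets: Sequence[tuple[int, int]]) -> frozenset[int]:
    """1-based indices of tokens overlapping [char_start, char_end)."""
    return frozenset(
        i + 1 for i, (lo, hi) in enumerate(offsets) if lo < char_end and hi > char_start
    )


def generate_candidates(
    corpus: Corpus,
    *,
    separator: str = "\t",
    splitter: Splitter | None = None,
    return_stats: bool = False,
):
    """Enumerate one example per (chemical, gene) mention pair per sentence.

    The label is the gold CPR group when an evaluated annotation links the
    pair; pairs annotated with a non-evaluated group, and unannotated pairs,
    are labeled negative.  Gold relations whose arguments sit in different
    sentences are dropped and counted.  Pairs whose mentions occupy exactly
    the same characters are dropped with a warning.
    """
    stats = CandidateStats()
    gold: dict[tuple[str, str, str], str] = {}
    for rel in corpus.relations:
        gold[(rel.doc_id, rel.arg1_id, rel.arg2_id)] = rel.cpr_group
    matched: set[tuple[str, str, str]] = set()
    examples: list[SentenceExample] = []
    for doc_id, doc in corpus.documents.items():
        mentions = corpus.doc_entities(doc_id)
        sentences = split_sentences(
            doc, mentions, separator=separator, splitter=splitter, stats=stats
        )
        for sent_index, (sent_text, (lo, hi)) in enumerate(sentences):
            inside = [m for m in mentions if m.start >= lo and m.end <= hi]
            chems = [m for m in inside if m.is_chemical]
            genes = [m for m in inside if m.is_gene]
            token_triplets = _whitespace_tokens(sent_text)
            if not token_triplets:
                continue
            tokens = [t[0] for t in token_triplets]
            offsets = [(t[1], t[2]) for t in token_triplets]
            heads = [0] + [1] * (len(tokens) - 1)  # provisional flat tree
            for chem in chems:
                for gene in genes:
                    if chem.start == gene.start and chem.end == gene.end:
                        stats.n_dropped_overlap += 1
                        warnings.warn(
                            f"{doc_id}: mentions {chem.entity_id}/{gene.entity_id} "
                            "overlap completely; pair dropped"
                        )
                        continue
                    chem_span = _project_span(chem.start - lo, chem.end - lo, offsets)
                    prot_span = _project_span(gene.start - lo, gene.end - lo, offsets)
                    if not chem_span or not prot_span:
                        raise AlignmentError(
                            f"{doc_id}/s{sent_index}: mention does not map onto tokens"
                        )
                    group = gold.get((doc_id, chem.entity_id, gene.entity_id))
                    if group is not None:
                        matched.add((doc_id, chem.entity_id, gene.entity_id))
                    label = group if group in EVALUATED_GROUPS else NEGATIVE_LABEL
                    example = SentenceExample(
                        doc_id=doc_id,
                        sent_index=sent_index,
                        text=sent_text,
                        sent_start=lo,
                        tokens=list(tokens),
                        pos_tags=[OUTSIDE_TAG] * len(tokens),
                        entity_tags=[OUTSIDE_TAG] * len(tokens),
                        heads=list(heads),
                        chem_span=chem_span,
                        prot_span=prot_span,
                        chem_id=chem.entity_id,
                        prot_id=gene.entity_id,
                        chem_char=(chem.start, chem.end),
                        prot_char=(gene.start, gene.end),
                        label=label,
                    )
                    examples.append(tag_entity_types(example))
    stats.n_candidates = len(examples)
    stats.n_cross_sentence_relations = sum(1 for key in gold if key not in matched)
    if return_stats:
        return examples, stats
    return examples


_DIGIT_RUN = re.compile(r"\d+")


def normalize_digits(example: SentenceExample, *, whole_token_only: bool = False) -> SentenceExample:
    """Replace digit strings outside the entity spans with the ``num`` tag.

    By default every maximal digit run inside a non-entity token is replaced
    ("p53" becomes "pnum"); with ``whole_token_only`` only tokens consisting
    entirely of digits are rewritten.  Entity tokens are never touched, so
    digit-bearing entity names survive.  Idempotent.
    """
    protected = example.chem_span | example.prot_span
    tokens = []
    for i, tok in enumerate(example.tokens, start=1):
        if i in protected:
            tokens.append(tok)
        elif whole_token_only:
            tokens.append("num" if _DIGIT_RUN.fullmatch(tok) else tok)
        else:
            tokens.append(_DIGIT_RUN.sub("num", tok))
    return replace(example, tokens=tokens)


def tag_entity_types(example: SentenceExample) -> SentenceExample:
    """Assign per-token tags: ``chemical`` / ``gen`` on the argument spans,
    ``O`` elsewhere.  Where the spans overlap (nested mentions), the shorter
    mention wins — the inner mention is the informative tag."""
    tags = [OUTSIDE_TAG] * example.n
    chem_first = len(example.chem_span) <= len(example.prot_span)
    order = (
        [(example.prot_span, GENE_TAG), (example.chem_span, CHEM_TAG)]
        if chem_first
        else [(example.chem_span, CHEM_TAG), (example.prot_span, GENE_TAG)]
    )
    for span, tag in order:  # shorter span written last, so it wins overlaps
        for i in span:
            tags[i - 1] = tag
    return replace(example, entity_tags=tags)


def _token_offsets_in(text: str, forms: Sequence[str], where: str) -> list[tuple[int, int]]:
    """Locate each parse token in the sentence text, left to right."""
    offsets = []
    cursor = 0
    for form in forms:
        pos = text.find(form, cursor)
        if pos < 0:
            raise AlignmentError(f"{where}: token {form!r} not found in sentence text")
        offsets.append((pos, pos + len(form)))
        cursor = pos + len(form)
    return offsets


def attach_parses(
    examples: Sequence[SentenceExample], conllu_path: str | Path
) -> list[SentenceExample]:
    """Replace each example's provisional tokenization with its dependency
    parse from a CoNLL-U file.

    Parses are matched by the ``doc_id`` / ``sent_index`` sentence comments;
    entity character spans are re-projected onto the parse tokens.  A missing
    or text-inconsistent parse raises :class:`AlignmentError` naming the
    sentence.
    """
    parses: dict[tuple[str, int], ConlluSentence] = {}
    for sent in read_conllu(conllu_path):
        if "doc_id" not in sent.metadata or "sent_index" not in sent.metadata:
            raise AlignmentError(
                f"{conllu_path}: sentence without doc_id/sent_index metadata"
            )
        parses[(sent.metadata["doc_id"], int(sent.metadata["sent_index"]))] = sent
    out: list[SentenceExample] = []
    for ex in examples:
        key = (ex.doc_id, ex.sent_index)
        if key not in parses:
            raise AlignmentError(f"no parse for sentence {ex.doc_id}/s{ex.sent_index}")
        parse = parses[key]
        offsets = _token_offsets_in(ex.text, parse.forms, f"{ex.doc_id}/s{ex.sent_index}")
        chem_span = _project_span(ex.chem_char[0] - ex.sent_start, ex.chem_char[1] - ex.sent_start, offsets)
        prot_span = _project_span(ex.prot_char[0] - ex.sent_start, ex.prot_char[1] - ex.sent_start, offsets)
        if not chem_span or not prot_span:
            raise AlignmentError(
                f"{ex.doc_id}/s{ex.sent_index}: entity span lost in re-tokenization"
            )
        updated = replace(
            ex,
            tokens=list(parse.forms),
            pos_tags=list(parse.pos),
            heads=list(parse.heads),
            entity_tags=[OUTSIDE_TAG] * parse.n,
            chem_span=chem_span,
            prot_span=prot_span,
        )
        out.append(tag_entity_types(updated))
    return out


def resplit(
    examples: Sequence[SentenceExample], spec: SplitSpec
) -> tuple[list[SentenceExample], list[SentenceExample]]:
    """Deterministic document-level train/dev split.

    No document contributes examples to both halves; the train fraction of
    documents is honoured to within one document.
    """
    doc_ids = sorted({ex.doc_id for ex in examples})
    rng = np.random.default_rng(spec.seed)
    order = [doc_ids[i] for i in rng.permutation(len(doc_ids))]
    n_train = int(round(spec.train_fraction * len(doc_ids)))
    if len(doc_ids) > 1:
        n_train = min(max(n_train, 1), len(doc_ids) - 1)
    train_docs = set(order[:n_train])
    train = [ex for ex in examples if ex.doc_id in train_docs]
    dev = [ex for ex in examples if ex.doc_id not in train_docs]
    return train, dev


def write_examples(examples: Sequence[SentenceExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(ex.to_json() + "\n")


def read_examples(path: str | Path) -> list[SentenceExample]:
    with open(path, encoding="utf-8") as fh:
        return [SentenceExample.from_json(line) for line in fh if line.strip()]
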