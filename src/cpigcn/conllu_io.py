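"""Minimal CoNLL-U reading and writing.

Only the columns this package consumes are modeled: FORM, UPOS and HEAD,
plus the sentence-level comment metadata used to align parses with corpus
sentences (``doc_id`` and ``sent_index``).  Multiword-token ranges and empty
nodes are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class ConlluError(ValueError):
    pass


@dataclass
class ConlluSentence:
    forms: list[str]
    pos: list[str]
    heads: list[int]
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.forms)


def read_conllu(path: str | Path) -> list[ConlluSentence]:
    sentences: list[ConlluSentence] = []
    current = ConlluSentence([], [], [])
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current.forms:
                    sentences.append(current)
                    current = ConlluSentence([], [], [])
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    current.metadata[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ConlluError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
            token_id = cols[0]
            if "-" in token_id or "." in token_id:
                continue  # multiword range or empty node
            if cols[6] in ("_", ""):
                raise ConlluError(f"{path}:{lineno}: token {cols[1]!r} has no head")
            try:
                head = int(cols[6])
            except ValueError as exc:
                raise ConlluError(f"{path}:{lineno}: non-integer head {cols[6]!r}") from exc
            current.forms.append(cols[1])
            current.pos.append(cols[3])
            current.heads.append(head)
    if current.forms:
        sentences.append(current)
    return sentences


def write_conllu(sentences: list[ConlluSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for key, value in sent.metadata.items():
                fh.write(f"# {key} = {value}\n")
            for i, (form, pos, head) in enumerate(zip(sent.forms, sent.pos, sent.heads), start=1):
                fh.write(f"{i}\t{form}\t_\t{pos}\t_\t_\t{head}\t_\t_\t_\n")
            fh.write("\n")
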