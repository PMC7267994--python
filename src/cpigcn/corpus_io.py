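"""Readers and writers for ChemProt-style corpora.

A corpus is distributed as three tab-separated files:

* ``abstracts``: ``doc_id<TAB>title<TAB>abstract``
* ``entities``:  ``doc_id<TAB>entity_id<TAB>type<TAB>start<TAB>end<TAB>surface``
* ``relations``: ``doc_id<TAB>CPR:k<TAB>[eval/type columns]<TAB>Arg1:Tn<TAB>Arg2:Tn``

Character offsets in the entities file are 0-based, end-exclusive, and are
computed over ``title + separator + abstract`` where the separator is a single
character (a tab in the official distribution; configurable because dialects
differ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The ten relation groups of the corpus.
CPR_GROUPS = tuple(f"CPR:{k}" for k in range(1, 11))

#: The five groups scored in evaluation.  All other groups (and unannotated
#: co-occurring pairs) count as negatives.
EVALUATED_GROUPS = frozenset({"CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9"})

#: Label used for a co-occurring pair with no evaluated gold relation.
NEGATIVE_LABEL = "NEG"

CHEMICAL_TYPE = "CHEMICAL"
GENE_TYPES = frozenset({"GENE-Y", "GENE-N", "GENE"})


class CorpusFormatError(ValueError):
    """A malformed line or a failed cross-file validation."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    abstract: str

    def text(self, separator: str = "\t") -> str:
        """Full document text over which entity offsets are defined."""
        return self.title + separator + self.abstract

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusFormatError("document with empty doc_id")


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    entity_id: str
    etype: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusFormatError(
                f"mention {self.doc_id}/{self.entity_id}: bad offsets [{self.start}, {self.end})"
            )

    @property
    def is_chemical(self) -> bool:
        return self.etype == CHEMICAL_TYPE

    @property
    def is_gene(self) -> bool:
        # GENE-Y and GENE-N are both treated as protein entities.
        return self.etype in GENE_TYPES


@dataclass(frozen=True)
class RelationAnnotation:
    doc_id: str
    cpr_group: str
    arg1_id: str  # chemical
    arg2_id: str  # gene/protein

    @property
    def evaluated(self) -> bool:
        return self.cpr_group in EVALUATED_GROUPS


@dataclass
class Corpus:
    documents: dict[str, Document] = field(default_factory=dict)
    entities: dict[str, dict[str, EntityMention]] = field(default_factory=dict)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def doc_entities(self, doc_id: str) -> list[EntityMention]:
        return list(self.entities.get(doc_id, {}).values())

    def get_entity(self, doc_id: str, entity_id: str) -> EntityMention:
        return self.entities[doc_id][entity_id]

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_entities(self) -> int:
        return sum(len(m) for m in self.entities.values())

    @property
    def n_relations(self) -> int:
        return len(self.relations)


def _split_line(line: str, path: str | Path, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise CorpusFormatError(
            f"{path}:{lineno}: expected at least {min_fields} tab-separated fields, got {len(fields)}"
        )
    return fields


def _parse_arg(value: str, path: str | Path, lineno: int, slot: str) -> str:
    if ":" not in value:
        raise CorpusFormatError(f"{path}:{lineno}: malformed {slot} field {value!r}")
    prefix, entity_id = value.split(":", 1)
    if prefix not in ("Arg1", "Arg2") or not entity_id:
        raise CorpusFormatError(f"{path}:{lineno}: malformed {slot} field {value!r}")
    return entity_id


def read_abstracts(path: str | Path) -> dict[str, Document]:
    documents: dict[str, Document] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 3)
            doc_id, title = fields[0], fields[1]
            # An abstract may legitimately contain stray tabs in some dumps;
            # glue any surplus fields back together.
            abstract = "\t".join(fields[2:])
            if doc_id in documents:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            documents[doc_id] = Document(doc_id=doc_id, title=title, abstract=abstract)
    return documents


def read_entities(
    path: str | Path,
    documents: dict[str, Document],
    *,
    separator: str = "\t",
    strict_offsets: bool = True,
) -> dict[str, dict[str, EntityMention]]:
    entities: dict[str, dict[str, EntityMention]] = {}
    for doc_id in documents:
        entities[doc_id] = {}
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 6)
            doc_id, entity_id, etype, start_s, end_s, surface = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: non-integer offsets") from exc
            if doc_id not in documents:
                n_dropped += 1
                warnings.warn(
                    f"{path}:{lineno}: mention {entity_id} references unknown doc {doc_id}; dropped"
                )
                continue
            mention = EntityMention(doc_id, entity_id, etype, start, end, surface)
            doc_text = documents[doc_id].text(separator)
            if doc_text[start:end] != surface:
                msg = (
                    f"{path}:{lineno}: mention {doc_id}/{entity_id} surface {surface!r} "
                    f"!= document slice {doc_text[start:end]!r}"
                )
                if strict_offsets:
                    raise CorpusFormatError(msg)
                warnings.warn(msg + "; dropped")
                n_dropped += 1
                continue
            if entity_id in entities[doc_id]:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate entity_id {doc_id}/{entity_id}")
            entities[doc_id][entity_id] = mention
    if n_dropped:
        logger.info("dropped %d unresolvable entity mentions from %s", n_dropped, path)
    return entities


def read_relations(
    path: str | Path, entities: dict[str, dict[str, EntityMention]]
) -> list[RelationAnnotation]:
    """Read a relations file, auto-detecting its dialect by column count.

    Accepted dialects (all tab-separated):

    * 4 columns: ``doc  group  Arg1:Tn  Arg2:Tn`` (prediction format)
    * 5 columns: ``doc  group  eval-flag/type  Arg1:Tn  Arg2:Tn``
    * 6 columns: ``doc  group  eval-flag  relation-type  Arg1:Tn  Arg2:Tn``
      (official gold standard)

    The trailing two columns always carry the arguments; anything between the
    group and the arguments is ignored — the ``evaluated`` flag is derived
    from group membership, which is its invariant definition.
    """
    relations: list[RelationAnnotation] = []
    seen: set[tuple[str, str, str, str]] = set()
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 4)
            if len(fields) > 6:
                raise CorpusFormatError(f"{path}:{lineno}: too many fields ({len(fields)})")
            doc_id, cpr_group = fields[0], fields[1]
            if cpr_group not in CPR_GROUPS:
                raise CorpusFormatError(f"{path}:{lineno}: unknown relation group {cpr_group!r}")
            arg1_id = _parse_arg(fields[-2], path, lineno, "Arg1")
            arg2_id = _parse_arg(fields[-1], path, lineno, "Arg2")
            if doc_id not in entities or arg1_id not in entities[doc_id] or arg2_id not in entities[doc_id]:
                n_dropped += 1
                warnings.warn(
                    f"{path}:{lineno}: relation references unresolvable entities "
                    f"({doc_id}, {arg1_id}, {arg2_id}); dropped"
                )
                continue
            key = (doc_id, cpr_group, arg1_id, arg2_id)
            if key in seen:
                warnings.warn(f"{path}:{lineno}: duplicate relation {key}; de-duplicated")
                continue
            seen.add(key)
            relations.append(RelationAnnotation(doc_id, cpr_group, arg1_id, arg2_id))
    if n_dropped:
        logger.info("dropped %d unresolvable relations from %s", n_dropped, path)
    return relations


def read_corpus(
    abstracts_path: str | Path,
    entities_path: str | Path,
    relations_path: str | Path | None = None,
    *,
    separator: str = "\t",
    strict_offsets: bool = True,
) -> Corpus:
    """Read a full corpus, enforcing cross-file invariants.

    ``relations_path`` may be ``None`` for unannotated corpora.  Records with
    unresolvable cross-references are dropped with a warning; offset/surface
    mismatches raise unless ``strict_offsets`` is disabled.
    """
    documents = read_abstracts(abstracts_path)
    entities = read_entities(entities_path, documents, separator=separator, strict_offsets=strict_offsets)
    relations: list[RelationAnnotation] = []
    if relations_path is not None:
        relations = read_relations(relations_path, entities)
    return Corpus(documents=documents, entities=entities, relations=relations)


def write_corpus(
    corpus: Corpus,
    abstracts_path: str | Path,
    entities_path: str | Path,
    relations_path: str | Path | None = None,
    *,
    gold_dialect: bool = True,
) -> None:
    """Write a corpus back to the three-file format read by :func:`read_corpus`."""
    with open(abstracts_path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents.values():
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")
    with open(entities_path, "w", encoding="utf-8") as fh:
        for doc_id in corpus.documents:
            for m in corpus.entities.get(doc_id, {}).values():
                fh.write(f"{m.doc_id}\t{m.entity_id}\t{m.etype}\t{m.start}\t{m.end}\t{m.surface}\n")
    if relations_path is None:
        return
    with open(relations_path, "w", encoding="utf-8") as fh:
        for rel in corpus.relations:
            if gold_dialect:
                flag = "Y" if rel.evaluated else "N"
                fh.write(
                    f"{rel.doc_id}\t{rel.cpr_group}\t{flag}\t{rel.cpr_group}\t"
                    f"Arg1:{rel.arg1_id}\tArg2:{rel.arg2_id}\n"
                )
            else:
                fh.write(f"{rel.doc_id}\t{rel.cpr_group}\tArg1:{rel.arg1_id}\tArg2:{rel.arg2_id}\n")


@dataclass(frozen=True)
class Prediction:
    """One predicted relation, serializable to the 4-column dialect."""

    doc_id: str
    cpr_group: str
    arg1_id: str
    arg2_id: str

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.doc_id, self.arg1_id, self.arg2_id, self.cpr_group)


def write_predictions(predictions: Iterable[Prediction], path: str | Path) -> None:
    """Write predictions as ``doc_id<TAB>CPR:k<TAB>Arg1:Tn<TAB>Arg2:Tn`` lines.

    Predictions with a non-evaluated class are rejected.
    """
    rows: Sequence[Prediction] = list(predictions)
    for p in rows:
        if p.cpr_group not in EVALUATED_GROUPS:
            raise ValueError(f"prediction with non-evaluated class {p.cpr_group!r}: {p}")
    with open(path, "w", encoding="utf-8") as fh:
        for p in rows:
            fh.write(f"{p.doc_id}\t{p.cpr_group}\tArg1:{p.arg1_id}\tArg2:{p.arg2_id}\n")


def read_predictions(path: str | Path) -> list[Prediction]:
    """Read a 4-column predictions file (no entity resolution)."""
    out: list[Prediction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 4)
            arg1 = _parse_arg(fields[2], path, lineno, "Arg1")
            arg2 = _parse_arg(fields[3], path, lineno, "Arg2")
            out.append(Prediction(fields[0], fields[1], arg1, arg2))
    return out
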