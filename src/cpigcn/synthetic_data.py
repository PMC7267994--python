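"""Synthetic ChemProt-format corpora with plantable relation signal.

Every sentence is instantiated from a hand-written template that carries its
own tokenization, POS tags and dependency tree, so no external parser is
ever needed.  Each positive pair's class is fully determined by a trigger
token drawn from a per-class lexicon, which makes near-perfect recovery by a
correct model possible.  Optional distractor clauses hang tokens off the
dependency path (some at distance 3, so pruning at N=2 removes them), and
template variants place the trigger directly on the path, one hop away, or
two hops away, which is what makes pruning sweeps meaningful.

Outputs are the standard three TSV files, a CoNLL-U parse file whose
sentence comments carry ``doc_id``/``sent_index``, and a JSON-lines
manifest recording ground truth (boundaries, spans, labels, trigger and
distractor positions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from cpigcn.conllu_io import ConlluSentence, write_conllu
from cpigcn.corpus_io import (
    Corpus,
    Document,
    EntityMention,
    NEGATIVE_LABEL,
    RelationAnnotation,
    write_corpus,
)
from cpigcn.depgraph import DependencyTree

DEFAULT_PREVALENCE = {
    "CPR:3": 0.14,
    "CPR:4": 0.18,
    "CPR:5": 0.12,
    "CPR:6": 0.12,
    "CPR:9": 0.14,
    NEGATIVE_LABEL: 0.30,
}

DEFAULT_LEXICON = {
    "CPR:3": ("activates", "upregulates", "activator"),
    "CPR:4": ("inhibits", "downregulates", "inhibitor"),
    "CPR:5": ("agonizes", "agonist"),
    "CPR:6": ("antagonizes", "antagonist"),
    "CPR:9": ("metabolizes", "substrate"),
}

#: Template ids usable for positive sentences.
POSITIVE_TEMPLATES = ("verb", "nominal", "offpath1", "offpath2")


@dataclass(frozen=True)
class SimSpec:
    n_documents: int = 100
    sentences_per_doc: tuple[int, int] = (2, 5)
    class_prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    trigger_lexicon: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_LEXICON))
    distractor_prob: float = 0.3
    nested_prob: float = 0.05
    digit_token_prob: float = 0.3
    template_pool: tuple[str, ...] = POSITIVE_TEMPLATES
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_prevalence.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_prevalence.values()):
            raise ValueError(f"class prevalences must be non-negative and sum to 1, got {total}")
        words: set[str] = set()
        for lex in self.trigger_lexicon.values():
            if words & set(lex):
                raise ValueError("trigger lexicons must be disjoint")
            words |= set(lex)
        unknown = set(self.template_pool) - set(POSITIVE_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates {sorted(unknown)}")


@dataclass
class SentencePlan:
    """One instantiated sentence with its ground truth."""

    template: str
    tokens: list[str]
    pos: list[str]
    heads: list[int]
    chem_span: tuple[int, ...]  # 1-based token indices, empty if no pair
    prot_span: tuple[int, ...]
    chem_name: str
    prot_name: str
    label: str
    trigger_index: int | None
    distractor_indices: tuple[int, ...]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


# Distractor clause hung off the protein token: a relative clause whose inner
# tokens sit at tree-distance 3 from the dependency path.
_DISTRACTOR_TOKENS = [",", "which", "was", "observed", "in", "many", "patients"]
_DISTRACTOR_POS = ["PUNCT", "PRON", "AUX", "VERB", "ADP", "ADJ", "NOUN"]


def _distractor(offset: int, prot_index: int, quantity: str) -> tuple[list[str], list[str], list[int], tuple[int, ...]]:
    """Build the distractor block starting at token ``offset + 1``.

    Internal heads (relative order): "," which was -> observed; observed ->
    protein; in many -> patients; patients -> observed.
    """
    tokens = list(_DISTRACTOR_TOKENS)
    tokens[5] = quantity  # "many" or a digit string
    verb = offset + 4
    patients = offset + 7
    heads = [verb, verb, verb, prot_index, patients, patients, verb]
    indices = tuple(range(offset + 1, offset + 8))
    return tokens, list(_DISTRACTOR_POS), heads, indices


def build_sentence(
    template: str,
    chem_name: str,
    prot_name: str,
    trigger: str | None,
    label: str,
    *,
    distractor: bool = False,
    quantity: str = "many",
) -> SentencePlan:
    """Instantiate a template into tokens, POS tags and a dependency tree."""
    if template == "verb":
        # CHEM TRIG PROT [distractor] .
        tokens = [chem_name, trigger, prot_name]
        pos = ["NOUN", "VERB", "NOUN"]
        heads = [2, 0, 2]
        chem, prot, trig, root = (1,), (3,), 2, 2
    elif template == "nominal":
        # CHEM is a TRIG of PROT [distractor] .
        tokens = [chem_name, "is", "a", trigger, "of", prot_name]
        pos = ["NOUN", "AUX", "DET", "NOUN", "ADP", "NOUN"]
        heads = [4, 4, 4, 0, 6, 4]
        chem, prot, trig, root = (1,), (6,), 4, 4
    elif template == "offpath1":
        # CHEM targets PROT [distractor] as a TRIG . — trigger 1 off the path
        tokens = [chem_name, "targets", prot_name]
        pos = ["NOUN", "VERB", "NOUN"]
        heads = [2, 0, 2]
        chem, prot, trig, root = (1,), (3,), None, 2
    elif template == "offpath2":
        # CHEM targets PROT [distractor] in a TRIG manner . — trigger 2 off
        tokens = [chem_name, "targets", prot_name]
        pos = ["NOUN", "VERB", "NOUN"]
        heads = [2, 0, 2]
        chem, prot, trig, root = (1,), (3,), None, 2
    elif template == "neg":
        # CHEM was measured with PROT [distractor] .
        tokens = [chem_name, "was", "measured", "with", prot_name]
        pos = ["NOUN", "AUX", "VERB", "ADP", "NOUN"]
        heads = [3, 3, 0, 5, 3]
        chem, prot, trig, root = (1,), (5,), None, 3
    elif template == "nested":
        # The CHEM PROT cotransporter was studied [distractor] .
        tokens = ["The", chem_name, prot_name, "cotransporter", "was", "studied"]
        pos = ["DET", "NOUN", "NOUN", "NOUN", "AUX", "VERB"]
        heads = [4, 4, 4, 6, 6, 0]
        chem, prot, trig, root = (2,), (2, 3, 4), None, 6
    else:
        raise ValueError(f"unknown template {template!r}")

    distractor_indices: tuple[int, ...] = ()
    if distractor:
        d_tokens, d_pos, d_heads, distractor_indices = _distractor(len(tokens), prot[-1], quantity)
        tokens += d_tokens
        pos += d_pos
        heads += d_heads

    if template == "offpath1":
        trig = len(tokens) + 3
        tokens += ["as", "a", trigger]
        pos += ["ADP", "DET", "NOUN"]
        heads += [trig, trig, root]
    elif template == "offpath2":
        manner = len(tokens) + 4
        trig = len(tokens) + 3
        tokens += ["in", "a", trigger, "manner"]
        pos += ["ADP", "DET", "NOUN", "NOUN"]
        heads += [manner, manner, manner, root]

    tokens.append(".")
    pos.append("PUNCT")
    heads.append(root)
    DependencyTree(heads)  # validate
    return SentencePlan(
        template=template,
        tokens=tokens,
        pos=pos,
        heads=heads,
        chem_span=chem,
        prot_span=prot,
        chem_name=chem_name,
        prot_name=prot_name,
        label=label,
        trigger_index=trig,
        distractor_indices=distractor_indices,
    )


@dataclass
class GeneratedCorpus:
    corpus: Corpus
    parses: list[ConlluSentence]
    manifest: list[dict]
    paths: dict[str, Path] | None = None


def generate_corpus(spec: SimSpec, out_dir: str | Path | None = None) -> GeneratedCorpus:
    """Generate a corpus; deterministic (byte-identical files) given the seed.

    When ``out_dir`` is given, writes ``abstracts.tsv``, ``entities.tsv``,
    ``relations.tsv``, ``parses.conllu`` and ``manifest.jsonl`` there.
    """
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_prevalence)
    probs = np.array([spec.class_prevalence[c] for c in classes])
    corpus = Corpus()
    parses: list[ConlluSentence] = []
    manifest: list[dict] = []

    for d in range(spec.n_documents):
        doc_id = f"D{10000 + d}"
        title = f"Synthetic document {d} ."
        lo_s, hi_s = spec.sentences_per_doc
        n_sentences = int(rng.integers(lo_s, hi_s + 1))
        plans: list[SentencePlan] = []
        for _ in range(n_sentences):
            chem_name = f"CHEM-{rng.integers(100, 1000)}"
            prot_name = f"PROT{rng.integers(10, 100)}"
            if rng.random() < spec.nested_prob:
                plans.append(build_sentence("nested", chem_name, prot_name, None, NEGATIVE_LABEL))
                continue
            label = classes[int(rng.choice(len(classes), p=probs))]
            has_distractor = rng.random() < spec.distractor_prob
            quantity = str(rng.integers(10, 100)) if rng.random() < spec.digit_token_prob else "many"
            if label == NEGATIVE_LABEL:
                plans.append(
                    build_sentence("neg", chem_name, prot_name, None, label,
                                   distractor=has_distractor, quantity=quantity)
                )
            else:
                template = spec.template_pool[int(rng.integers(len(spec.template_pool)))]
                trigger = spec.trigger_lexicon[label][int(rng.integers(len(spec.trigger_lexicon[label])))]
                plans.append(
                    build_sentence(template, chem_name, prot_name, trigger, label,
                                   distractor=has_distractor, quantity=quantity)
                )

        abstract = " ".join(p.text for p in plans)
        corpus.documents[doc_id] = Document(doc_id=doc_id, title=title, abstract=abstract)
        corpus.entities[doc_id] = {}
        boundaries = [(0, len(title))]
        parses.append(
            ConlluSentence(
                forms=title.split(), pos=["ADJ", "NOUN", "NUM", "PUNCT"], heads=[2, 0, 2, 2],
                metadata={"doc_id": doc_id, "sent_index": "0"},
            )
        )
        manifest.append({
            "doc_id": doc_id, "sent_index": 0, "template": "title", "text": title,
            "start": 0, "end": len(title), "label": None,
        })

        offset = len(title) + 1  # title + tab separator
        entity_counter = 0
        for s, plan in enumerate(plans, start=1):
            sent_start = offset
            token_offsets = []
            cursor = sent_start
            for tok in plan.tokens:
                token_offsets.append((cursor, cursor + len(tok)))
                cursor += len(tok) + 1
            sent_end = sent_start + len(plan.text)
            boundaries.append((sent_start, sent_end))
            offset = sent_end + 1

            def _register(span: tuple[int, ...], etype: str) -> str:
                nonlocal entity_counter
                entity_counter += 1
                entity_id = f"T{entity_counter}"
                start = token_offsets[span[0] - 1][0]
                end = token_offsets[span[-1] - 1][1]
                surface = " ".join(plan.tokens[i - 1] for i in span)
                corpus.entities[doc_id][entity_id] = EntityMention(
                    doc_id=doc_id, entity_id=entity_id, etype=etype,
                    start=start, end=end, surface=surface,
                )
                return entity_id

            chem_id = _register(plan.chem_span, "CHEMICAL")
            gene_type = "GENE-Y" if rng.random() < 0.5 else "GENE-N"
            prot_id = _register(plan.prot_span, gene_type)
            if plan.label != NEGATIVE_LABEL:
                corpus.relations.append(
                    RelationAnnotation(doc_id, plan.label, chem_id, prot_id)
                )
            elif plan.template == "nested":
                # Non-evaluated PART_OF-style gold annotation; the candidate
                # pair must come out labeled negative downstream.
                corpus.relations.append(RelationAnnotation(doc_id, "CPR:1", chem_id, prot_id))
            parses.append(
                ConlluSentence(
                    forms=list(plan.tokens), pos=list(plan.pos), heads=list(plan.heads),
                    metadata={"doc_id": doc_id, "sent_index": str(s)},
                )
            )
            manifest.append({
                "doc_id": doc_id, "sent_index": s, "template": plan.template,
                "text": plan.text, "start": sent_start, "end": sent_end,
                "tokens": plan.tokens, "heads": plan.heads,
                "chem_span": list(plan.chem_span), "prot_span": list(plan.prot_span),
                "chem_id": chem_id, "prot_id": prot_id, "label": plan.label,
                "trigger_index": plan.trigger_index,
                "distractor_indices": list(plan.distractor_indices),
            })

    paths = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "abstracts": out / "abstracts.tsv",
            "entities": out / "entities.tsv",
            "relations": out / "relations.tsv",
            "conllu": out / "parses.conllu",
            "manifest": out / "manifest.jsonl",
        }
        write_corpus(corpus, paths["abstracts"], paths["entities"], paths["relations"])
        write_conllu(parses, paths["conllu"])
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            for row in manifest:
                fh.write(json.dumps(row) + "\n")
    return GeneratedCorpus(corpus=corpus, parses=parses, manifest=manifest, paths=paths)


def generate_examples(spec: SimSpec):
    """Generate a corpus on disk and run the full preprocessing pipeline.

    Round-trips through the TSV/CoNLL-U formats deliberately, so the file
    plumbing is exercised.  Returns ``(examples, generated_corpus)``.
    """
    import tempfile

    from cpigcn.corpus_io import read_corpus
    from cpigcn.preprocessing import attach_parses, generate_candidates, normalize_digits

    with tempfile.TemporaryDirectory() as tmp:
        gen = generate_corpus(spec, tmp)
        corpus = read_corpus(gen.paths["abstracts"], gen.paths["entities"], gen.paths["relations"])
        examples = generate_candidates(corpus)
        examples = attach_parses(examples, gen.paths["conllu"])
        examples = [normalize_digits(ex) for ex in examples]
    gen.paths = None  # the temporary files are gone
    return examples, gen


#: Fixed toy trees for unit tests: (heads, chem_span, prot_span).
_UNIT_TREES: dict[str, tuple[list[int], tuple[int, ...], tuple[int, ...]]] = {
    "svo": ([3, 3, 0, 5, 3], (1,), (4, 5)),
}


def generate_unit_tree(template_id: str) -> tuple[DependencyTree, frozenset[int], frozenset[int]]:
    """Return a fixed toy tree with entity spans, by template id.

    Besides the hand-picked ``svo`` tree, every sentence template is
    available as ``<name>`` or ``<name>+distractor``.
    """
    if template_id in _UNIT_TREES:
        heads, chem, prot = _UNIT_TREES[template_id]
        return DependencyTree(heads), frozenset(chem), frozenset(prot)
    name, _, suffix = template_id.partition("+")
    if name in POSITIVE_TEMPLATES + ("neg", "nested") and suffix in ("", "distractor"):
        trigger = "trigger" if name in POSITIVE_TEMPLATES else None
        label = "CPR:4" if trigger else NEGATIVE_LABEL
        plan = build_sentence(name, "CHEM-1", "PROT2", trigger, label,
                              distractor=(suffix == "distractor"))
        return DependencyTree(plan.heads), frozenset(plan.chem_span), frozenset(plan.prot_span)
    raise KeyError(f"unknown unit-tree template {template_id!r}")
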