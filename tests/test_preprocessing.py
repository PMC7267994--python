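import json

import numpy as np
import pytest

from cpigcn import preprocessing
from cpigcn.conllu_io import ConlluSentence, write_conllu
from cpigcn.corpus_io import Document, read_corpus
from cpigcn.preprocessing import (
    AlignmentError,
    SentenceExample,
    SplitSpec,
    attach_parses,
    generate_candidates,
    normalize_digits,
    resplit,
    split_sentences,
    tag_entity_types,
)
from conftest import write_corpus_files


def make_example(tokens, chem_span, prot_span, heads=None, label="NEG", **kw):
    n = len(tokens)
    heads = heads if heads is not None else [0] + [1] * (n - 1)
    defaults = dict(
        doc_id="D1", sent_index=1, text=" ".join(tokens), sent_start=0,
        tokens=list(tokens), pos_tags=["X"] * n, entity_tags=["O"] * n,
        heads=heads, chem_span=frozenset(chem_span), prot_span=frozenset(prot_span),
        chem_id="T1", prot_id="T2", chem_char=(0, 1), prot_char=(2, 3), label=label,
    )
    defaults.update(kw)
    return SentenceExample(**defaults)


class TestSplitSentences:
    def test_two_sentences(self):
        doc = Document("D1", "Title .", "A is B. C is D.")
        parts = split_sentences(doc)
        texts = [t for t, _ in parts]
        assert texts == ["Title .", "A is B.", "C is D."]

    def test_ranges_are_ordered_disjoint_slices(self):
        doc = Document("D1", "Title .", "A is B. C is D. E is F.")
        parts = split_sentences(doc)
        text = doc.text()
        prev_end = -1
        for sent_text, (lo, hi) in parts:
            assert text[lo:hi] == sent_text
            assert lo > prev_end
            prev_end = hi

    def test_mention_spanning_boundary_repaired(self, tmp_path):
        # "B. C" region covered by a mention forces the two sentences to merge.
        doc = Document("D1", "T .", "A is B. C is D.")
        from cpigcn.corpus_io import EntityMention

        start = doc.text().index("B. C")
        m = EntityMention("D1", "T1", "CHEMICAL", start, start + 4, "B. C")
        parts = split_sentences(doc, [m])
        covering = [(lo, hi) for _, (lo, hi) in parts if lo <= m.start and m.end <= hi]
        assert len(covering) == 1

    def test_generator_boundaries_match_ground_truth(self, tmp_path):
        from cpigcn.synthetic_data import SimSpec, generate_corpus

        gen = generate_corpus(SimSpec(n_documents=1, sentences_per_doc=(3, 3), seed=5))
        doc = next(iter(gen.corpus.documents.values()))
        mentions = gen.corpus.doc_entities(doc.doc_id)
        parts = split_sentences(doc, mentions)
        truth = [(r["start"], r["end"]) for r in gen.manifest if r["doc_id"] == doc.doc_id]
        assert [rng for _, rng in parts] == truth
        assert len(truth) == 4  # title + 3 abstract sentences


class TestGenerateCandidates:
    def test_two_chems_one_gene_all_negative(self, tmp_path):
        title = "T ."
        abstract = "ChemA and ChemB bind GeneX ."
        text = title + "\t" + abstract

        def off(s):
            i = text.index(s)
            return i, i + len(s)

        rows = [("D1", "T1", "CHEMICAL", *off("ChemA"), "ChemA"),
                ("D1", "T2", "CHEMICAL", *off("ChemB"), "ChemB"),
                ("D1", "T3", "GENE-N", *off("GeneX"), "GeneX")]
        paths = write_corpus_files(tmp_path, [("D1", title, abstract)], rows, [])
        corpus = read_corpus(paths["abstracts"], paths["entities"], paths["relations"])
        examples = generate_candidates(corpus)
        assert len(examples) == 2
        assert all(ex.label == "NEG" for ex in examples)

    def test_antagonism_sentence_labeled_cpr6(self, tmp_path):
        title = "T ."
        abstract = "Alprenolol caused antagonism of beta 1-adrenoceptor responses ."
        text = title + "\t" + abstract

        def off(s):
            i = text.index(s)
            return i, i + len(s)

        rows = [("D1", "T1", "CHEMICAL", *off("Alprenolol"), "Alprenolol"),
                ("D1", "T2", "GENE-Y", *off("beta 1-adrenoceptor"), "beta 1-adrenoceptor")]
        rels = [("D1", "CPR:6", "Y", "ANTAGONIST", "Arg1:T1", "Arg2:T2")]
        paths = write_corpus_files(tmp_path, [("D1", title, abstract)], rows, rels)
        corpus = read_corpus(paths["abstracts"], paths["entities"], paths["relations"])
        examples = generate_candidates(corpus)
        assert len(examples) == 1
        assert examples[0].label == "CPR:6"

    def test_cross_sentence_gold_dropped_and_counted(self, tmp_path):
        title = "T ."
        abstract = "ChemA is here. GeneX is there."
        text = title + "\t" + abstract

        def off(s):
            i = text.index(s)
            return i, i + len(s)

        rows = [("D1", "T1", "CHEMICAL", *off("ChemA"), "ChemA"),
                ("D1", "T2", "GENE-Y", *off("GeneX"), "GeneX")]
        rels = [("D1", "CPR:4", "Y", "INHIBITOR", "Arg1:T1", "Arg2:T2")]
        paths = write_corpus_files(tmp_path, [("D1", title, abstract)], rows, rels)
        corpus = read_corpus(paths["abstracts"], paths["entities"], paths["relations"])
        examples, stats = generate_candidates(corpus, return_stats=True)
        assert examples == []
        assert stats.n_cross_sentence_relations == 1

    def test_non_evaluated_gold_group_becomes_negative(self, small_examples, small_generated):
        nested = [r for r in small_generated.manifest if r["template"] == "nested"]
        assert nested  # generator fixture includes nested mentions
        keys = {(r["doc_id"], r["sent_index"]) for r in nested}
        got = [ex for ex in small_examples if (ex.doc_id, ex.sent_index) in keys]
        assert got and all(ex.label == "NEG" for ex in got)

    def test_candidate_count_invariant(self, small_corpus):
        examples, stats = generate_candidates(small_corpus, return_stats=True)
        expected = 0
        for doc_id, doc in small_corpus.documents.items():
            mentions = small_corpus.doc_entities(doc_id)
            for _, (lo, hi) in split_sentences(doc, mentions):
                inside = [m for m in mentions if m.start >= lo and m.end <= hi]
                n_chem = sum(m.is_chemical for m in inside)
                n_gene = sum(m.is_gene for m in inside)
                expected += n_chem * n_gene
        assert len(examples) == expected - stats.n_dropped_overlap


class TestNormalizeDigits:
    def test_plain_digit_token(self):
        ex = make_example(["Dose", "50", "given"], {1}, {3})
        assert normalize_digits(ex).tokens == ["Dose", "num", "given"]

    def test_entity_token_untouched(self):
        ex = make_example(["BMS-354825", "inhibits", "SRC"], {1}, {3})
        assert normalize_digits(ex).tokens == ["BMS-354825", "inhibits", "SRC"]

    def test_digit_run_inside_token(self):
        ex = make_example(["x", "p53", "y"], {1}, {3})
        assert normalize_digits(ex).tokens == ["x", "pnum", "y"]

    def test_whole_token_mode(self):
        ex = make_example(["x", "p53", "50"], {1}, {2})
        got = normalize_digits(ex, whole_token_only=True)
        assert got.tokens == ["x", "p53", "num"]

    def test_idempotent(self):
        ex = make_example(["a1b2", "50", "x"], {3}, {3})
        once = normalize_digits(ex)
        assert normalize_digits(once).tokens == once.tokens


class TestTagEntityTypes:
    def test_basic_tags(self):
        ex = make_example(list("abcde"), {1}, {4, 5})
        got = tag_entity_types(ex)
        assert got.entity_tags == ["chemical", "O", "O", "gen", "gen"]

    def test_tag_counts_match_span_sizes(self):
        ex = make_example(list("abcdefg"), {2, 3}, {5, 6, 7})
        got = tag_entity_types(ex)
        assert got.entity_tags.count("chemical") == 2
        assert got.entity_tags.count("gen") == 3

    def test_nested_shorter_mention_wins(self):
        # chemical nested inside a longer gene mention
        tokens = ["thiazide-sensitive", "sodium-chloride", "cotransporter"]
        ex = make_example(tokens, {2}, {1, 2, 3})
        got = tag_entity_types(ex)
        assert got.entity_tags == ["gen", "chemical", "gen"]


class TestAttachParses:
    def _conllu(self, tmp_path, sentences):
        path = tmp_path / "parses.conllu"
        write_conllu(sentences, path)
        return path

    def test_heads_roundtrip(self, tmp_path):
        ex = make_example(["A", "binds", "B", "."], {1}, {3},
                          chem_char=(0, 1), prot_char=(8, 9), sent_start=0,
                          text="A binds B .")
        parse = ConlluSentence(["A", "binds", "B", "."], ["N", "V", "N", "P"], [2, 0, 2, 2],
                               {"doc_id": "D1", "sent_index": "1"})
        got = attach_parses([ex], self._conllu(tmp_path, [parse]))
        assert got[0].heads == [2, 0, 2, 2]
        assert got[0].pos_tags == ["N", "V", "N", "P"]

    def test_char_span_covering_two_tokens(self, tmp_path):
        text = "beta blocker binds B ."
        ex = make_example(text.split(), {1, 2}, {4},
                          chem_char=(0, 12), prot_char=(19, 20), sent_start=0, text=text)
        parse = ConlluSentence(text.split(), ["N"] * 5, [2, 3, 0, 3, 3],
                               {"doc_id": "D1", "sent_index": "1"})
        got = attach_parses([ex], self._conllu(tmp_path, [parse]))
        assert got[0].chem_span == frozenset({1, 2})

    def test_retokenization_reprojects_spans(self, tmp_path):
        # The parser splits "B." into two tokens; spans must follow.
        text = "A binds B."
        ex = make_example(["A", "binds", "B."], {1}, {3},
                          chem_char=(0, 1), prot_char=(8, 9), sent_start=0, text=text)
        parse = ConlluSentence(["A", "binds", "B", "."], ["N", "V", "N", "P"], [2, 0, 2, 2],
                               {"doc_id": "D1", "sent_index": "1"})
        got = attach_parses([ex], self._conllu(tmp_path, [parse]))
        assert got[0].prot_span == frozenset({3})
        assert got[0].n == 4

    def test_missing_parse_is_alignment_error(self, tmp_path):
        ex = make_example(["A", "binds", "B"], {1}, {3})
        parse = ConlluSentence(["A"], ["N"], [0], {"doc_id": "D9", "sent_index": "1"})
        with pytest.raises(AlignmentError, match="D1/s1"):
            attach_parses([ex], self._conllu(tmp_path, [parse]))

    def test_misordered_parse_text_mismatch_raises(self, tmp_path):
        ex = make_example(["A", "binds", "B"], {1}, {3}, text="A binds B")
        wrong = ConlluSentence(["Totally", "different"], ["N", "N"], [0, 1],
                               {"doc_id": "D1", "sent_index": "1"})
        with pytest.raises(AlignmentError):
            attach_parses([ex], self._conllu(tmp_path, [wrong]))

    def test_token_without_head_rejected(self, tmp_path):
        path = tmp_path / "bad.conllu"
        path.write_text("1\tA\t_\tN\t_\t_\t_\t_\t_\t_\n\n")
        from cpigcn.conllu_io import ConlluError, read_conllu

        with pytest.raises(ConlluError, match="no head"):
            read_conllu(path)


class TestResplit:
    def _examples(self, n_docs, per_doc=3):
        out = []
        for d in range(n_docs):
            for s in range(per_doc):
                out.append(make_example(["a", "b", "c"], {1}, {3}, doc_id=f"D{d}", sent_index=s))
        return out

    def test_nine_one_split(self):
        examples = self._examples(10)
        train, dev = resplit(examples, SplitSpec(seed=3))
        assert len({ex.doc_id for ex in train}) == 9
        assert len({ex.doc_id for ex in dev}) == 1

    def test_same_seed_identical(self):
        examples = self._examples(17)
        a = resplit(examples, SplitSpec(seed=8))
        b = resplit(examples, SplitSpec(seed=8))
        assert [ex.key() for ex in a[0]] == [ex.key() for ex in b[0]]
        assert [ex.key() for ex in a[1]] == [ex.key() for ex in b[1]]

    def test_no_document_in_both_halves_100_random(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_docs = int(rng.integers(2, 30))
            examples = self._examples(n_docs, per_doc=int(rng.integers(1, 4)))
            train, dev = resplit(examples, SplitSpec(seed=int(rng.integers(10_000))))
            assert not ({ex.doc_id for ex in train} & {ex.doc_id for ex in dev})
            assert len(train) + len(dev) == len(examples)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(seed=0, train_fraction=1.0)


class TestPipelineInvariants:
    def test_length_invariants_preserved(self, small_examples):
        for ex in small_examples:
            ex.validate()
            assert len(ex.tokens) == len(ex.pos_tags) == len(ex.entity_tags) == len(ex.heads)

    def test_json_roundtrip(self, small_examples, tmp_path):
        path = tmp_path / "examples.jsonl"
        preprocessing.write_examples(small_examples, path)
        back = preprocessing.read_examples(path)
        assert [ex.to_json() for ex in back] == [ex.to_json() for ex in small_examples]
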