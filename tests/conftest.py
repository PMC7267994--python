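import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from cpigcn import corpus_io, preprocessing
from cpigcn.synthetic_data import SimSpec, generate_corpus


@pytest.fixture(scope="session")
def small_generated(tmp_path_factory):
    """A 30-document synthetic corpus written to disk, with its manifest."""
    out = tmp_path_factory.mktemp("corpus")
    gen = generate_corpus(SimSpec(n_documents=30, seed=11), out)
    return gen


@pytest.fixture(scope="session")
def small_corpus(small_generated):
    return corpus_io.read_corpus(
        small_generated.paths["abstracts"],
        small_generated.paths["entities"],
        small_generated.paths["relations"],
    )


@pytest.fixture(scope="session")
def small_examples(small_generated, small_corpus):
    examples = preprocessing.generate_candidates(small_corpus)
    examples = preprocessing.attach_parses(examples, small_generated.paths["conllu"])
    return [preprocessing.normalize_digits(ex) for ex in examples]


def write_corpus_files(tmp_path, abstracts, entities, relations):
    """Write raw TSV rows to the three corpus files; returns paths."""
    paths = {}
    for name, rows in (("abstracts", abstracts), ("entities", entities), ("relations", relations)):
        path = tmp_path / f"{name}.tsv"
        path.write_text("".join("\t".join(str(c) for c in row) + "\n" for row in rows))
        paths[name] = path
    return paths
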