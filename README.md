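# cpigcn

Sentence-level chemical–protein interaction (CPI) extraction: a relation
classifier that combines a bidirectional LSTM encoder with a graph
convolutional network (GCN) over path-centric-pruned dependency trees,
plus the ChemProt-style corpus tooling, a synthetic-corpus generator, and
micro-averaged F-score evaluation.

## What is inside

| Module | Purpose |
| --- | --- |
| `cpigcn.corpus_io` | Read/write ChemProt-style abstracts / entities / relations TSV files and prediction files, with cross-file validation. |
| `cpigcn.preprocessing` | Sentence splitting, candidate-pair generation (one example per co-occurring chemical/gene mention pair), digit normalization, entity-type tagging, CoNLL-U parse attachment, document-level 9:1 re-split. |
| `cpigcn.depgraph` | Dependency-tree algorithms: LCA of two spans, dependency path, path-centric pruning at distance `N` (0, 1, 2, 3 or ∞), and self-looped, degree-normalized adjacency construction. |
| `cpigcn.model` | The neural scorer: word/POS/entity-type embedding concatenation, Bi-LSTM, L-layer GCN (`h_i = relu((Σ_j Ã_ij W h_j)/d_i + b)`), entity-aware max-pooling, FFNN + softmax. Both encoder stages are ablatable config switches. |
| `cpigcn.training_eval` | SGD training (learning rate 0.3, gradient-norm clipping) with early stopping on dev micro-F, prediction, micro-averaged P/R/F, pruning/feature sweeps. |
| `cpigcn.synthetic_data` | Templated corpus generator (TSV + CoNLL-U + manifest) with trigger-word-determined labels, off-path triggers and distractor clauses, so everything is testable with no download. |
| `cpigcn.autograd` | Minimal reverse-mode autodiff over numpy (no deep-learning framework is required at runtime). |

The model is built in pure numpy: parameters are float64, every operation is
deterministic given the seeds, and the backward pass is validated against
finite differences in the test suite.

## CLI

```bash
cpigcn simulate   --out corpus/ --n-docs 100 --seed 0      # synthetic corpus
cpigcn preprocess --abstracts corpus/abstracts.tsv --entities corpus/entities.tsv \
                  --relations corpus/relations.tsv --conllu corpus/parses.conllu \
                  --out examples.jsonl
cpigcn train      --train train.jsonl --dev dev.jsonl --model-out model.npz \
                  --config config.json --epochs 20 --log run.json
cpigcn predict    --examples dev.jsonl --model model.npz --out preds.tsv
cpigcn evaluate   --gold dev.jsonl --predictions preds.tsv
cpigcn sweep      --train train.jsonl --dev dev.jsonl --grid pruning
cpigcn prune      --conllu corpus/parses.conllu --sentence 1 \
                  --chem-span 1 --prot-span 3 -n 2          # inspect pruning
```

`config.json` holds `ModelConfig` fields (`word_dim`, `pos_dim`,
`etype_dim`, `lstm_hidden`, `gcn_hidden`, `gcn_layers`, `prune_distance`,
`dropout`, feature switches …); unlisted fields keep the tuned defaults
(200/20/60 embedding dims, 200 hidden units, learning rate 0.3, dropout
0.5). Pretrained word vectors in word2vec/FastText text format can be
passed to `cpigcn train --word-vectors vectors.txt`.

## Real ChemProt data

`read_corpus` accepts the official distribution's three TSV files per split
(entity offsets over `title + tab + abstract`; both the 4-column and the
gold 5/6-column relations dialects are auto-detected). Dependency parses
are ingested from CoNLL-U produced by any parser; sentence comments must
carry `doc_id` and `sent_index` matching the package's sentence splitter.

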