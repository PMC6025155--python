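# kitm

Knowledge-involved topic modeling for patient-reported posts from online
health communities, built on a medical terminology graph.

The package provides:

* **A terminology knowledge base** (`kitm.knowledge_base`) — concepts with
  codes, synonyms, semantic types; typed relations; an acyclic IS_A
  hierarchy — with readers for a pipe-delimited RRF dialect
  (MRCONSO/MRREL column conventions, configurable) and a self-contained
  TSV dialect (grammar below).
* **A post/corpus model** (`kitm.corpus_model`) with CSV and JSON-Lines
  round-tripping and a packaged five-post example corpus.
* **A tokenizer + filter chain** (`kitm.text_pipeline`): tokenize on
  space/punctuation, lowercase, words-and-numbers only, then minimum term
  length (3), document-frequency threshold (4), dynamic 30-term stoplist,
  minimum document length (5), and a 10-document label filter.
* **Concept encoding** (`kitm.concept_encoding`): rule-based POS tagging,
  domain discovery of labels against the KB, and greedy longest-match
  dictionary encoding of tokens to concept quadruples
  (knowledge source, code, semantic type, preferred name).
* **Latent knowledge expansion** (`kitm.knowledge_expansion`):
  descriptive/semantic relation-item extraction and exact-distance-layer
  expansion over the hierarchy (layers 1..m), appending latent concepts'
  preferred names to the token stream.
* **Labeled LDA with CVB0 inference** (`kitm.model`): topics identified
  one-to-one with labels, document-topic support restricted exactly to
  each document's labels, zero-order collapsed variational updates,
  fold-in inference, document-completion held-out perplexity, per-topic
  top terms.
* **Knowledge-rate metrics** (`kitm.metrics`): explicit knowledge rate
  (EKR), latent knowledge rate (LKR, reachable-set default plus a literal
  path-count mode), knowledge correlation rate (KCR).
* **A synthetic generator** (`kitm.synthetic_data`) producing toy KBs and
  labeled corpora with known topic structure, so every stage is testable
  offline with a controllable explicit-knowledge rate.

## CLI

All stages are subcommands of `kitm`:

```sh
kitm synth --config synth.yaml --seed 5 \
     --out-kb kb.tsv --out-corpus corpus.jsonl --out-truth truth.json
kitm preprocess --corpus corpus.jsonl --out tokenized.jsonl
kitm encode     --tokenized tokenized.jsonl --kb kb.tsv --out encoded.jsonl
kitm expand     --encoded encoded.jsonl --kb kb.tsv --layers 1 --out expanded.jsonl
kitm train      --dataset expanded.jsonl --labels labels.jsonl \
                --alpha 0.1 --beta 0.01 --iters 200 --seed 7 --out model.json
kitm topics     --model model.json --top 5
kitm evaluate   --encoded encoded.jsonl --kb kb.tsv --m 1 --m 2 --m 3 --out report.csv
kitm run        --config run.yaml          # full pipeline + manifest
kitm build-kb   --conso MRCONSO.RRF --rel MRREL.RRF --out kb.tsv
```

`kitm run` reads a single YAML file (every flag overrides it):

```yaml
corpus_path: corpus.jsonl
corpus_format: jsonl
kb_path: kb.tsv
pipeline: {min_term_length: 3, term_min_doc_count: 4,
           label_min_doc_count: 10, stoplist_size: 30, doc_min_length: 5}
m: 1
alpha: 0.1
beta: 0.01
iterations: 200
seed: 7
out_dir: out
```

It writes every intermediate artifact plus `run_manifest.json` with input
hashes, the seed, per-stage record counts and output hashes; re-running
with the same seed is bitwise reproducible (manifest timestamp aside).

## Toy KB TSV grammar

```
file      := header? concepts relations?
header    := "#" ... "name=" kbname NEWLINE
concepts  := "[CONCEPTS]" NEWLINE concept-row*
concept-row := code TAB source TAB preferred_name TAB synonyms TAB semantic_type NEWLINE
synonyms  := term ("|" term)*          ; preferred_name is implicitly a synonym
relations := "[RELATIONS]" NEWLINE relation-row*
relation-row := source_code TAB label TAB target_code NEWLINE
```

Relations are stored directed and traversed undirected by default
(`KbConfig.directed_traversal`). The IS_A slice must be acyclic; cyclic
input is rejected at load time.

Packaged fixtures under `kitm/data/`: `toy_kb.tsv` (a drug/condition
mini-ontology), `table2_posts.csv` (five example posts),
`mini_conso.rrf` / `mini_rel.rrf` (a 12-concept RRF-dialect sample).

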