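# bioir

Ranked retrieval with query expansion and linear rank fusion for biomedical
literature search.

Biomedical search queries rarely use the same vocabulary as the articles
that answer them — a query about *NF-kappaB activation* may miss relevant
papers that only ever write *RelA signalling*. `bioir` is a compact,
fully-tested implementation of the classic experimental loop used to study
this problem: index a document collection, retrieve a TF-IDF baseline,
expand each query by several techniques, fuse pairs of result lists, and
measure everything by Mean Average Precision (MAP) on TREC-format runs and
qrels. It is aimed at IR students and researchers who want a transparent,
dependency-light testbed rather than a production search engine.

## The model

Documents and queries pass through one normalisation pipeline (HTML-tag
stripping, tokenisation, stopword removal, Porter stemming). A document *d*
is scored against a weighted query *q* by

    score(q, d) = Σ_t  w_q(t) · log(1 + tf_{t,d}) · log(N / df_t)

where `tf_{t,d}` is the term's frequency in *d*, `df_t` its document
frequency and `N` the collection size.

Four query-expansion techniques produce weighted expanded queries:

* **Most frequent terms (MFT)** — pseudo-relevance feedback: count term
  frequencies over the top `doc_count` documents of an initial run and
  append the `term_count` most frequent non-query terms with unit weight.
* **Relevance model (Lavrenko)** — estimate `P(w|R) = Σ_d ω_d · P(w|d)`
  over the top `fbDocs` feedback documents, with Dirichlet-smoothed document
  language models and document weights `ω_d` proportional to each document's
  query likelihood; keep the `fbTerms` most probable terms and interpolate
  with the original query by `fbOrigWeight` (RM3 style).
* **Thesaurus / dictionary expansion** — frequent-term extraction from
  per-topic candidate texts supplied by the user (e.g. concept-recognizer
  output, or abstracts fetched from a literature database), either a fixed
  number of terms or up to ten in "unordered" mode.

Two runs are fused per topic by the convex combination

    L.C. = α · Score1 + (1 − α) · Score2

over the union of their document lists (missing score = 0, per-topic
min-max normalisation by default), and α is swept over 0.1 … 0.9 selecting
the best document MAP.

A synthetic benchmark generator produces topic-structured corpora with
controllable vocabulary mismatch, so the whole loop is testable without any
external collection. See `docs/methods.md` for the generative model and all
numerical conventions.

## Worked example

```bash
bioir synth --out bench --seed 11 --n-topics 4 --docs-per-topic 5 --background-docs 30
bioir index  --corpus bench/corpus --out index.jsonl
bioir search --index index.jsonl --topics bench/topics.tsv --out baseline.txt
bioir eval   --run baseline.txt --qrels bench/qrels.txt
```

prints

```
MAP     0.8227  (4 topics)
```

the document-level MAP of the TF-IDF baseline over the four generated
topics. Expanding with the relevance model and fusing recovers most of the
relevant documents the mismatched queries miss:

```bash
bioir expand --technique rm --index index.jsonl --topics bench/topics.tsv \
             --initial-run baseline.txt --out rm.txt
bioir fuse   --run1 baseline.txt --run2 rm.txt --qrels bench/qrels.txt \
             --out fused.txt --table alpha.tsv
bioir eval   --run fused.txt --qrels bench/qrels.txt
```

```
MAP     0.9027  (4 topics)
```

`alpha.tsv` holds the per-α MAP table of the sweep. The same operations are
available as library functions (`bioir.search`, `bioir.mft_expand`,
`bioir.relevance_model_expand`, `bioir.resource_expand`,
`bioir.sweep_alpha`, `bioir.mean_average_precision`, …).

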