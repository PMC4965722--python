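# Methods

This note records the models implemented in `bioir`, the conventions and
defaults that matter for reproducing its numbers, and what the synthetic
benchmark does and does not establish about real collections.

## Preprocessing

Documents and queries share one pipeline: markup stripping, tokenisation,
stopword removal, Porter stemming. Sharing the pipeline is a correctness
requirement, not a convenience — a query term can only match an index term
if both were normalised identically.

* **Markup stripping** removes `<...>` spans outright (a tag never closed
  swallows the rest of the string) and decodes HTML entities. Inter-tag
  text is preserved in order.
* **Tokenisation** splits on every character that is not an ASCII letter or
  digit, lowercases, and drops purely numeric tokens and tokens shorter
  than 2 characters. This keeps gene symbols (`p53`, `brca1`) intact while
  splitting hyphenated forms (`NF-kappaB` → `nf`, `kappab`). Splitting
  hyphenated biomedical tokens is a deliberate, documented choice; both
  halves index consistently on the query and document sides, so matching is
  unaffected.
* **Stopwords**: the packaged list is the 318-word Glasgow IR English stop
  list, a standard general-English IR list; any file of one word per line
  can be substituted via configuration.
* **Stemming** is the classic five-step Porter algorithm, in the form
  maintained by its author (including the two standard revisions to step 2).
  A no-op mode exists for experiments on already-normalised text. Only
  Porter is provided: it is the strong-stemming choice conventional in
  biomedical IR pipelines of this design, and a second (weak) stemmer would
  not change any interface.

Re-preprocessing preprocessed text is a fixed point except for the few
stems that are not themselves stemmer fixed points (e.g. `relate` → `relat`
only after the first pass); the test suite pins this exception class down.

## Indexing and retrieval

The inverted index stores postings with within-document term frequencies,
document frequencies, collection frequencies, per-document lengths and the
collection size. Document length is measured after stopword removal and
stemming so that the feedback language models and `tf` live on the same
event space. Postings are kept sorted by document id, which — together
with the explicit score tie-break below — makes every run bit-reproducible.

Scoring is the log-TF × log-IDF product

    W_{t,d} = log(1 + tf_{t,d}) · log(N / df_t)

summed over query terms and multiplied by the query-side term weight (1.0
for ordinary terms; expansion techniques assign other weights). Numerical
conventions, each pinned for reproducibility:

* natural logarithm by default (`base10` available; the base rescales
  scores but can never reorder documents);
* documents scoring exactly 0 are omitted from runs;
* ties are broken by ascending document id;
* result lists are truncated to `count` (default 1000) per topic;
* no document-length normalisation of the TF component — the plain
  formula above, as stated, without pivoted-length correction.

## Query expansion

**Most frequent terms.** Term frequencies are summed over the top
`doc_count` (default 10) documents of the initial run; original query terms
are excluded (stopwords never reach the index); the `term_count` (default
10) highest totals are appended with weight 1.0, ties resolved
alphabetically. Unit weights — plain concatenation of the new terms onto
the query — are the documented choice; no reweighting is applied.

**Relevance model.** RM1 estimation with RM3-style interpolation:

    P(w|R) = Σ_{d ∈ F} ω_d · (tf_{w,d} + μ·P(w|C)) / (|d| + μ)

over the top `fbDocs` (default 5) feedback documents, where `P(w|C)` is the
maximum-likelihood collection model and μ (default 2500, the customary
Dirichlet mass for document-length text) smooths each document model. The
document weight `ω_d` is the softmax of the query log-likelihood under each
smoothed document model, normalised over the feedback set. `P(w|R)` is a
proper distribution over the index vocabulary (the suite checks Σ = 1 to
1e-9). The `fbTerms` (default 10) most probable non-query terms are kept;
original terms are rescaled to total weight `fbOrigWeight` (default 0.5)
and expansion terms share `1 − fbOrigWeight` proportionally to `P(w|R)`.
Consequences used as tests: document scores are affine in `fbOrigWeight`
for fixed term sets, and `fbOrigWeight = 1` reproduces the unexpanded
ranking exactly.

**Resource expansion.** Per-topic candidate texts (thesaurus output,
database abstracts, or any other term source) are preprocessed with the
standard pipeline and mined for frequent terms exactly like MFT, with two
modes: a fixed term count, or an "unordered" mode returning up to 10 terms
— fewer when the candidate text has fewer distinct eligible terms. The cap
of 10 makes the unordered mode deterministic. Candidate-text acquisition
(concept recognisers, literature APIs) is out of scope; the module consumes
pre-fetched text only.

## Fusion

Two runs are combined per topic as `α·s1 + (1−α)·s2` over the union of
their document lists, a missing score counting as 0 (the CombSUM
convention). Because raw TF-IDF sums and interpolated feedback scores live
on different scales, scores are min-max normalised to [0,1] per topic
before combining; raw-score fusion is retained as an option, and every
fusion property asserted by the suite holds in both modes. One consequence
of min-max normalisation worth knowing: the weakest-scoring document of a
topic maps to 0 and therefore ties with documents absent from that run, so
the α→0/1 endpoints reproduce the source ranking exactly only in raw mode.
The α sweep evaluates document MAP on the 0.1 … 0.9 grid and returns the
best α, preferring the smallest on ties (deterministic, and minimally
favouring the second run).

## Evaluation

Average Precision uses the standard definition with the total number of
judged-relevant documents in the denominator and a rank cutoff of 1000
(matching the default result depth). Relevance grade > 0 counts as
relevant; unjudged documents are non-relevant; topics with no judged
relevant document are excluded from the MAP mean (trec-eval convention)
and reported as skipped. Run files are six-column TREC format with scores
serialised at fixed 6-decimal precision, so write→read is an identity.
Percent improvement is `100·(MAP_new − MAP_ref)/MAP_ref` rounded to two
decimals.

## Synthetic benchmark

The generator emulates the structure this pipeline exists to exploit — and
nothing more. A vocabulary of synthetic tokens (`term00042`) is split into
per-topic blocks of `topic_term_count` (default 10) terms plus background
vocabulary. Documents are multinomial bags with Poisson lengths (mean 150):

* Each of the `docs_per_topic` (default 10) relevant documents of a topic
  boosts a per-document random subset of `active_topic_terms` (default 2)
  of its topic's block by a factor `on_topic_boost` (default 300) over
  background probability — about 8 occurrences of each active term and
  ~11 % on-topic tokens in a 150-token document. The per-document subset
  models the empirical fact that each article uses its own bursty slice of
  a topic's vocabulary; it is precisely what creates vocabulary mismatch.
* Background documents (default 200) draw uniformly from the full
  vocabulary.
* Each topic's query reveals a `1 − mismatch_rate` fraction of its block
  (default mismatch 0.5, i.e. 5-term queries); the withheld terms are
  recoverable only through expansion. At these defaults roughly a fifth of
  relevant documents share no term with their query and are invisible to
  the baseline.
* Candidate texts contain the full topic block (three occurrences per
  term) plus uniform noise, standing in for idealised thesaurus or
  dictionary material.
* Qrels mark exactly the topic's generated documents relevant; 36 topics
  by default.

Synthetic tokens pass through stemming and stopword removal unchanged; an
optional noise mode sprinkles English stopwords and pluralised token
variants through the text to exercise the full pipeline.

**What passing shows, and what it does not.** On this benchmark the
feedback expansions and the fused runs recover relevant documents the
mismatched queries miss, and the end-to-end suite verifies that their mean
MAP over ten seeded replicates is at least the baseline's, following the
study design of sweeping each technique's attribute grid (MFT term count
over 5–30; feedback original-query weight over 0.1–0.9) and comparing the
best-evaluated setting. This establishes that the machinery — statistics,
estimation, weighting, fusion, evaluation — behaves as designed under a
controlled mismatch mechanism. It does not establish effect sizes on real
biomedical text: the generator has uniform background frequencies rather
than Zipfian ones, no term co-occurrence structure beyond topic blocks, no
near-relevant distractor documents, and idealised candidate texts (which
is why resource expansion performs far better here, relative to the
baseline, than hand-curated resources do in practice).

## Problem sizes

The default experiment (36 topics, 560 documents, vocabulary 5000) is
sized so that a full ten-replicate acceptance run — indexing, baseline,
all four expansion techniques with their grids, and two fusion sweeps —
completes in about a minute on one CPU while leaving every statistic
(df, cf, idf, smoothing) in a regime where the models are exercised
non-trivially.

## Known limitations

* Single-field indexing only; no structured or field-scoped queries.
* No BM25 or other alternative weighting; the scorer is intentionally the
  single formula above.
* Fusion combines exactly two runs at a time (as does the α sweep);
  multi-run fusion schemes such as CombMNZ are not provided.
* Document-level MAP only; passage- and aspect-level evaluation require
  gold standards outside this package's scope.
* The Porter stemmer and tokenizer assume ASCII/English text.
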