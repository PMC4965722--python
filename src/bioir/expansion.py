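"""Query expansion: most-frequent-terms feedback, the Lavrenko relevance
model, and frequent-term extraction from external candidate texts.

Four techniques share one output type, :class:`ExpandedQuery`:

* ``mft`` — pseudo-relevance feedback that counts raw term frequencies over
  the top-ranked documents of an initial run and appends the most frequent
  non-query terms with unit weight.
* ``relevance_model`` — RM1 estimation of P(w|R) over the top feedback
  documents with Dirichlet-smoothed document language models, interpolated
  RM3-style with the original query through ``fb_orig_weight``.
* ``metamap_style`` / ``pubmed_style`` — frequent-term extraction from
  per-topic candidate texts supplied by the user (e.g. concept-recognizer
  output or abstracts fetched from a literature database), appended with
  unit weight. Either a fixed number of terms is taken, or in "unordered"
  mode up to ten, fewer when the candidate text is poorer than that.

The relevance model over the feedback set F for query q is

    P(w|R) = sum over d in F of  omega_d * P(w|d)
    P(w|d) = (tf_wd + mu * P(w|C)) / (|d| + mu)          (Dirichlet smoothing)
    omega_d  proportional to  exp(log P(q|d))            (query likelihood,
                                                          normalised over F)

P(w|R) is a proper distribution over the index vocabulary (it sums to one
before truncation). The kept expansion terms receive total weight
(1 - fb_orig_weight) distributed proportionally to P(w|R); the original
query terms are rescaled to total weight fb_orig_weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Final, Mapping

from .index import InvertedIndex
from .preprocess import PipelineConfig, preprocess
from .retrieval import QueryTopic, Run, SearchConfig, search

__all__ = [
    "UNORDERED",
    "MFTConfig",
    "FeedbackConfig",
    "ResourceConfig",
    "ExpandedQuery",
    "mft_expand",
    "relevance_model_expand",
    "resource_expand",
    "load_candidate_texts",
    "run_expanded",
]

logger = logging.getLogger(__name__)

#: Sentinel for resource expansion without a fixed term count (up to 10 terms).
UNORDERED: Final[str] = "unordered"


@dataclass(frozen=True)
class MFTConfig:
    """Most-frequent-terms feedback: top ``doc_count`` docs, ``term_count`` terms."""

    doc_count: int = 10
    term_count: int = 10

    def __post_init__(self) -> None:
        if self.doc_count < 1:
            raise ValueError("doc_count must be >= 1")
        if self.term_count < 0:
            raise ValueError("term_count must be >= 0")


@dataclass(frozen=True)
class FeedbackConfig:
    """Relevance-model parameters (fbDocs / fbTerms / fbOrigWeight + Dirichlet mu)."""

    fb_docs: int = 5
    fb_terms: int = 10
    fb_orig_weight: float = 0.5
    mu: float = 2500.0

    def __post_init__(self) -> None:
        if self.fb_docs < 1 or self.fb_terms < 1:
            raise ValueError("fb_docs and fb_terms must be >= 1")
        if not 0.0 <= self.fb_orig_weight <= 1.0:
            raise ValueError("fb_orig_weight must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class ResourceConfig:
    """Candidate-text expansion: per-topic texts plus a term count or UNORDERED."""

    candidate_texts: Mapping[str, str] = field(default_factory=dict)
    term_count: int | str = UNORDERED
    unordered_cap: int = 10

    def __post_init__(self) -> None:
        if self.term_count != UNORDERED and (
                not isinstance(self.term_count, int) or self.term_count < 1):
            raise ValueError("term_count must be a positive integer or UNORDERED")


@dataclass(frozen=True)
class ExpandedQuery:
    """Original terms plus weighted expansion terms from one technique."""

    topic_id: str
    original: tuple[tuple[str, float], ...]
    expansion: tuple[tuple[str, float], ...]
    provenance: str

    def __post_init__(self) -> None:
        orig = {t for t, _ in self.original}
        if any(t in orig for t, _ in self.expansion):
            raise ValueError("expansion terms must be disjoint from original terms")
        if any(w <= 0 for _, w in self.original + self.expansion):
            raise ValueError("query term weights must be positive")

    def as_query(self) -> QueryTopic:
        return QueryTopic(self.topic_id, "", self.original + self.expansion)


def _top_ranked_docs(initial_run: Run, topic_id: str, wanted: int) -> list[str]:
    entries = initial_run.for_topic(topic_id)
    if not entries:
        raise ValueError(f"initial run has no results for topic {topic_id!r}")
    if len(entries) < wanted:
        logger.warning("topic %s: only %d feedback docs available (wanted %d)",
                       topic_id, len(entries), wanted)
    return [e.doc_id for e in entries[:wanted]]


def _top_terms(counts: Mapping[str, float], k: int) -> list[str]:
    """Highest-count terms; ties broken alphabetically."""
    return [t for t, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]


def mft_expand(initial_run: Run, index: InvertedIndex, query: QueryTopic,
               config: MFTConfig | None = None) -> ExpandedQuery:
    """Append the terms most frequent in the top-ranked feedback documents.

    Term frequencies are summed over the top ``doc_count`` documents of the
    initial run; original query terms are excluded (stopwords never reach
    the index); the ``term_count`` highest totals are appended with unit
    weight, ties resolved alphabetically.
    """
    if config is None:
        config = MFTConfig()
    original_terms = {t for t, _ in query.terms}
    counts: dict[str, int] = {}
    for doc_id in _top_ranked_docs(initial_run, query.topic_id, config.doc_count):
        for term, tf in index.doc_vector(doc_id).items():
            if term not in original_terms:
                counts[term] = counts.get(term, 0) + tf
    chosen = _top_terms(counts, config.term_count)
    return ExpandedQuery(query.topic_id, query.terms,
                         tuple((t, 1.0) for t in chosen), "mft")


def relevance_model_probabilities(index: InvertedIndex, doc_ids: list[str],
                                  query: QueryTopic, mu: float) -> dict[str, float]:
    """P(w|R) over the whole index vocabulary for the given feedback set."""
    lengths = {d: index.doc_length(d) for d in doc_ids}
    # document weights: softmax of the query log-likelihood under each
    # Dirichlet-smoothed document model
    loglik = {}
    for d in doc_ids:
        ll = 0.0
        for term, qweight in query.terms:
            p = (index.doc_vector(d).get(term, 0) + mu * index.collection_prob(term)) \
                / (lengths[d] + mu) if (lengths[d] + mu) > 0 else 0.0
            ll += qweight * math.log(p) if p > 0 else qweight * -700.0
        loglik[d] = ll
    m = max(loglik.values())
    raw = {d: math.exp(loglik[d] - m) for d in doc_ids}
    z = sum(raw.values())
    omega = {d: raw[d] / z for d in doc_ids}

    # P(w|R) = sum_d omega_d (tf_wd + mu P(w|C)) / (|d|+mu)
    #        = [sum_d omega_d tf_wd/(|d|+mu)] + P(w|C) * sum_d omega_d mu/(|d|+mu)
    smooth_mass = sum(omega[d] * mu / (lengths[d] + mu) for d in doc_ids
                      if (lengths[d] + mu) > 0)
    probs: dict[str, float] = {}
    for d in doc_ids:
        denom = lengths[d] + mu
        if denom <= 0:
            continue
        w_d = omega[d]
        for term, tf in index.doc_vector(d).items():
            probs[term] = probs.get(term, 0.0) + w_d * tf / denom
    if smooth_mass:
        for term in index.vocabulary:
            probs[term] = probs.get(term, 0.0) + smooth_mass * index.collection_prob(term)
    return probs


def relevance_model_expand(initial_run: Run, index: InvertedIndex,
                           query: QueryTopic,
                           config: FeedbackConfig | None = None) -> ExpandedQuery:
    """RM1 + RM3-style interpolation pseudo-relevance feedback."""
    if config is None:
        config = FeedbackConfig()
    doc_ids = _top_ranked_docs(initial_run, query.topic_id, config.fb_docs)
    probs = relevance_model_probabilities(index, doc_ids, query, config.mu)
    original_terms = {t for t, _ in query.terms}
    candidates = {t: p for t, p in probs.items() if t not in original_terms and p > 0}
    chosen = _top_terms(candidates, config.fb_terms)

    orig_total = sum(w for _, w in query.terms)
    original = tuple((t, w * config.fb_orig_weight / orig_total) for t, w in query.terms)
    exp_mass = 1.0 - config.fb_orig_weight
    chosen_total = sum(candidates[t] for t in chosen)
    if exp_mass > 0 and chosen_total > 0:
        expansion = tuple((t, exp_mass * candidates[t] / chosen_total) for t in chosen)
    else:
        expansion = ()
    if config.fb_orig_weight == 0.0:
        original = ()
    return ExpandedQuery(query.topic_id, original, expansion, "relevance_model")


def resource_expand(query: QueryTopic, config: ResourceConfig,
                    pipeline: PipelineConfig | None = None,
                    provenance: str = "metamap_style") -> ExpandedQuery:
    """Frequent-term expansion from a per-topic candidate text.

    The candidate text is run through the standard preprocessing pipeline,
    term frequencies are counted, original query terms are excluded, and
    either the fixed ``term_count`` top terms or (UNORDERED mode) up to
    ``unordered_cap`` terms are appended with unit weight.
    """
    if query.topic_id not in config.candidate_texts:
        raise KeyError(f"no candidate text for topic {query.topic_id!r}")
    terms = preprocess(config.candidate_texts[query.topic_id], pipeline)
    original_terms = {t for t, _ in query.terms}
    counts: dict[str, int] = {}
    for term in terms:
        if term not in original_terms:
            counts[term] = counts.get(term, 0) + 1
    k = config.unordered_cap if config.term_count == UNORDERED else int(config.term_count)
    chosen = _top_terms(counts, k)
    return ExpandedQuery(query.topic_id, query.terms,
                         tuple((t, 1.0) for t in chosen), provenance)


def load_candidate_texts(path) -> dict[str, str]:
    """Load per-topic candidate texts.

    ``path`` is either a directory with one ``<topic_id>.txt`` file per
    topic, or a two-column TSV file ``topic_id <TAB> text``.
    """
    from pathlib import Path

    path = Path(path)
    texts: dict[str, str] = {}
    if path.is_dir():
        for p in sorted(path.glob("*.txt")):
            texts[p.stem] = p.read_text(encoding="utf-8")
    else:
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'topic_id<TAB>text'")
            topic_id, text = line.split("\t", 1)
            texts[topic_id.strip()] = text
    return texts


def run_expanded(expanded: ExpandedQuery, index: InvertedIndex,
                 config: SearchConfig | None = None, run_id: str = "expanded") -> Run:
    """Execute the expanded, weighted query exactly like a plain search."""
    return search(expanded.as_query(), index, config, run_id)
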