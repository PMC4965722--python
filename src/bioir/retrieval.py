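"""TF-IDF ranked retrieval producing TREC-format runs.

A document d is scored against a (possibly weighted) query q as

    score(q, d) = sum over query terms t of  w_q(t) * log(1 + tf_td) * log(N / df_t)

where tf_td is the term's frequency in d, df_t its document frequency and N
the collection size. Original query terms carry weight 1.0; expansion
techniques may attach other weights. The log base (natural by default) only
rescales scores and never changes a ranking, but it is pinned in
:class:`SearchConfig` so that score files reproduce bit-identically.

Documents scoring exactly zero are omitted; ties are broken by ascending
doc_id; results are truncated to ``count`` (default 1000) per topic.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from .index import InvertedIndex
from .preprocess import PipelineConfig, preprocess

__all__ = [
    "SearchConfig",
    "QueryTopic",
    "RunEntry",
    "Run",
    "tfidf_weight",
    "score_document",
    "search",
    "batch_search",
    "read_topics_tsv",
    "read_topics_trec",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Result depth and log base for the TF-IDF scorer."""

    count: int = 1000
    log_base: str = "natural"  # or "base10"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.log_base not in ("natural", "base10"):
            raise ValueError(f"unknown log_base {self.log_base!r}")

    def log(self, x: float) -> float:
        return math.log10(x) if self.log_base == "base10" else math.log(x)


@dataclass(frozen=True)
class QueryTopic:
    """A topic: identifier, free text, and weighted preprocessed terms."""

    topic_id: str
    text: str
    terms: tuple[tuple[str, float], ...]

    @classmethod
    def from_text(cls, topic_id: str, text: str,
                  config: PipelineConfig | None = None) -> "QueryTopic":
        terms = preprocess(text, config)
        return cls(topic_id, text, tuple((t, 1.0) for t in terms))


@dataclass(frozen=True)
class RunEntry:
    topic_id: str
    doc_id: str
    rank: int
    score: float
    run_id: str


@dataclass
class Run:
    """Per-topic ranked lists, grouped by topic_id."""

    run_id: str
    entries: dict[str, list[RunEntry]] = field(default_factory=dict)

    def topics(self) -> list[str]:
        return list(self.entries)

    def for_topic(self, topic_id: str) -> list[RunEntry]:
        return self.entries.get(topic_id, [])

    def add_topic(self, topic_id: str, entries: list[RunEntry]) -> None:
        if topic_id in self.entries:
            raise ValueError(f"duplicate topic_id {topic_id!r} in run")
        self.entries[topic_id] = entries

    def all_entries(self) -> Iterator[RunEntry]:
        for topic_id in self.entries:
            yield from self.entries[topic_id]

    def validate(self) -> None:
        for topic_id, rows in self.entries.items():
            seen: set[str] = set()
            for i, e in enumerate(rows):
                if e.rank != i + 1:
                    raise ValueError(f"non-consecutive rank for topic {topic_id}")
                if i and rows[i - 1].score < e.score:
                    raise ValueError(f"scores increase with rank for topic {topic_id}")
                if e.doc_id in seen:
                    raise ValueError(f"duplicate doc {e.doc_id} for topic {topic_id}")
                seen.add(e.doc_id)


def tfidf_weight(tf: int, df: int, n_docs: int,
                 config: SearchConfig | None = None) -> float:
    """log(1 + tf) * log(N / df); zero when tf = 0 or df = N."""
    if config is None:
        config = SearchConfig()
    if df <= 0 or n_docs <= 0:
        raise ValueError("tfidf_weight requires df >= 1 and N >= 1")
    if df > n_docs:
        raise ValueError("df cannot exceed N")
    if tf == 0:
        return 0.0
    return config.log(1 + tf) * config.log(n_docs / df)


def score_document(query: QueryTopic, doc_id: str, index: InvertedIndex,
                   config: SearchConfig | None = None) -> float:
    """Sum of query-weighted TF-IDF weights; unseen terms contribute zero."""
    if config is None:
        config = SearchConfig()
    vector = index.doc_vector(doc_id)
    total = 0.0
    for term, qweight in query.terms:
        df = index.df(term)
        if df == 0:
            continue
        tf = vector.get(term, 0)
        if tf:
            total += qweight * tfidf_weight(tf, df, index.n_docs, config)
    return total


def _ranked_entries(topic_id: str, scores: dict[str, float],
                    count: int, run_id: str) -> list[RunEntry]:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:count]
    return [RunEntry(topic_id, doc_id, rank, score, run_id)
            for rank, (doc_id, score) in enumerate(ordered, start=1)]


def search(query: QueryTopic, index: InvertedIndex,
           config: SearchConfig | None = None, run_id: str = "run") -> Run:
    """Rank the collection against one topic.

    Accumulates scores over postings of the query terms, so only documents
    containing at least one query term (the only ones with non-zero score)
    are considered.
    """
    if config is None:
        config = SearchConfig()
    run = Run(run_id)
    scores: dict[str, float] = {}
    for term, qweight in query.terms:
        stats, postings = index.lookup(term)
        if stats.df == 0 or stats.df == index.n_docs:
            continue
        for posting in postings:
            w = qweight * tfidf_weight(posting.tf, stats.df, index.n_docs, config)
            if w:
                scores[posting.doc_id] = scores.get(posting.doc_id, 0.0) + w
    scores = {d: s for d, s in scores.items() if s > 0.0}
    if not query.terms:
        logger.warning("topic %s is empty after preprocessing; empty result", query.topic_id)
    run.add_topic(query.topic_id, _ranked_entries(query.topic_id, scores, config.count, run_id))
    return run


def batch_search(topics: Sequence[QueryTopic], index: InvertedIndex,
                 config: SearchConfig | None = None, run_id: str = "run") -> Run:
    """Independent per-topic searches merged into one run."""
    ids = [t.topic_id for t in topics]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate topic_id in batch")
    run = Run(run_id)
    for topic in topics:
        single = search(topic, index, config, run_id)
        run.add_topic(topic.topic_id, single.for_topic(topic.topic_id))
    return run


# -- topic file readers ------------------------------------------------------

def read_topics_tsv(path: str | Path,
                    config: PipelineConfig | None = None) -> list[QueryTopic]:
    """One topic per line: ``topic_id <TAB> free text``."""
    topics = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'topic_id<TAB>text'")
        topic_id, text = line.split("\t", 1)
        topics.append(QueryTopic.from_text(topic_id.strip(), text.strip(), config))
    return topics


_TOP_RE = re.compile(r"<top>(.*?)</top>", re.S)
_NUM_RE = re.compile(r"<num>\s*(?:Number:)?\s*([^<\n]*)")
_TITLE_RE = re.compile(r"<title>\s*([^<\n]*)")


def read_topics_trec(path: str | Path,
                     config: PipelineConfig | None = None) -> list[QueryTopic]:
    """Reader for TREC-style ``<top>/<num>/<title>`` topic files."""
    topics = []
    for match in _TOP_RE.finditer(Path(path).read_text(encoding="utf-8")):
        body = match.group(1)
        num = _NUM_RE.search(body)
        title = _TITLE_RE.search(body)
        if num is None or title is None:
            raise ValueError("<top> block without <num> or <title>")
        topics.append(QueryTopic.from_text(num.group(1).strip(), title.group(1).strip(), config))
    return topics
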