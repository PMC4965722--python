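"""Topic-structured synthetic benchmark generator.

Emulates, at desk scale, the shape of a literature-retrieval test
collection: a set of topics, each with a block of "on-topic" vocabulary; a
pool of relevant documents per topic whose term distribution puts elevated
probability (``on_topic_boost``) on that topic's vocabulary; background
documents drawn uniformly from the full vocabulary; queries that reveal only
a fraction of each topic's vocabulary (``mismatch_rate`` withholds the
rest, creating the vocabulary mismatch query expansion exists to bridge);
per-topic candidate texts rich in the full on-topic vocabulary, standing in
for thesaurus or literature-database material; and qrels marking each
topic's generated documents as relevant.

Documents are multinomial bags of synthetic tokens ("term00042") with
Poisson lengths. Such tokens are untouched by stemming and stopword removal;
an optional noise mode sprinkles English stopwords and pluralised token
variants through the text to exercise the preprocessing pipeline too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import Qrels, write_qrels
from .retrieval import QueryTopic

__all__ = ["SyntheticSpec", "SyntheticBenchmark", "generate", "write_benchmark"]

_NOISE_STOPWORDS = ("the", "of", "and", "in", "to", "with", "for", "is")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults mirror a 36-topic collection.

    ``on_topic_boost`` is the ratio of an on-topic term's probability to a
    background term's probability inside a relevant document.
    ``active_topic_terms`` controls vocabulary heterogeneity: each relevant
    document boosts only that many terms of its topic's block, drawn at
    random per document (``None`` boosts the whole block in every relevant
    document). Real articles use their own bursty subset of a topic's
    vocabulary; this is what makes some relevant documents share no term
    with the query, the mismatch that expansion techniques must bridge.
    ``mismatch_rate`` is the fraction of each topic's vocabulary withheld
    from its query text.
    """

    n_topics: int = 36
    docs_per_topic: int = 10
    n_background_docs: int = 200
    vocab_size: int = 5000
    topic_term_count: int = 10
    on_topic_boost: float = 300.0
    active_topic_terms: int | None = 2
    doc_length_mean: int = 150
    mismatch_rate: float = 0.5
    seed: int = 0
    inject_noise_tokens: bool = False

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.docs_per_topic < 1 or self.vocab_size < 1:
            raise ValueError("n_topics, docs_per_topic and vocab_size must be >= 1")
        if self.topic_term_count < 1:
            raise ValueError("topic_term_count must be >= 1")
        if self.topic_term_count * self.n_topics > self.vocab_size:
            raise ValueError("topic_term_count * n_topics exceeds vocab_size")
        if self.on_topic_boost <= 1.0:
            raise ValueError("on_topic_boost must exceed 1")
        if self.active_topic_terms is not None and not (
                1 <= self.active_topic_terms <= self.topic_term_count):
            raise ValueError("active_topic_terms must lie in [1, topic_term_count]")
        if not 0.0 <= self.mismatch_rate <= 1.0:
            raise ValueError("mismatch_rate must lie in [0, 1]")
        if self.n_background_docs < 0 or self.doc_length_mean < 1:
            raise ValueError("invalid document counts or length")


@dataclass
class SyntheticBenchmark:
    documents: list[tuple[str, str]]
    topics: list[tuple[str, str]]  # (topic_id, query text)
    qrels: Qrels
    candidate_texts: dict[str, str]
    spec: SyntheticSpec = field(repr=False, default=None)

    def query_topics(self, pipeline_config=None) -> list[QueryTopic]:
        return [QueryTopic.from_text(tid, text, pipeline_config)
                for tid, text in self.topics]


def _token(i: int) -> str:
    return f"term{i:05d}"


def _doc_text(rng: np.random.Generator, token_ids: np.ndarray,
              spec: SyntheticSpec) -> str:
    tokens = [_token(i) for i in token_ids]
    if spec.inject_noise_tokens:
        # pluralise ~10% of tokens and interleave stopwords; both must be
        # undone by the preprocessing pipeline
        tokens = [t + "s" if rng.random() < 0.1 else t for t in tokens]
        n_stop = max(1, len(tokens) // 10)
        for pos in rng.integers(0, len(tokens) + 1, size=n_stop):
            tokens.insert(int(pos), str(rng.choice(_NOISE_STOPWORDS)))
    return " ".join(tokens)


def generate(spec: SyntheticSpec) -> SyntheticBenchmark:
    """Generate a benchmark, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    vocab = np.arange(spec.vocab_size)
    topic_blocks = {
        f"{t + 1:03d}": vocab[t * spec.topic_term_count:(t + 1) * spec.topic_term_count]
        for t in range(spec.n_topics)
    }

    documents: list[tuple[str, str]] = []
    judgments: dict[str, dict[str, int]] = {}
    topics: list[tuple[str, str]] = []
    candidate_texts: dict[str, str] = {}

    for topic_id, block in topic_blocks.items():
        judgments[topic_id] = {}
        for j in range(spec.docs_per_topic):
            doc_id = f"REL-{topic_id}-{j + 1:03d}"
            # each relevant document boosts its own subset of the topic block
            if spec.active_topic_terms is None:
                active = block
            else:
                active = rng.choice(block, size=spec.active_topic_terms,
                                    replace=False)
            probs = np.ones(spec.vocab_size)
            probs[active] = spec.on_topic_boost
            probs /= probs.sum()
            length = max(1, rng.poisson(spec.doc_length_mean))
            token_ids = rng.choice(vocab, size=length, p=probs)
            documents.append((doc_id, _doc_text(rng, token_ids, spec)))
            judgments[topic_id][doc_id] = 1

        # query: reveal a (1 - mismatch_rate) fraction of the topic block
        n_query = max(1, int(round((1.0 - spec.mismatch_rate) * len(block))))
        query_ids = rng.choice(block, size=n_query, replace=False)
        topics.append((topic_id, " ".join(_token(i) for i in sorted(query_ids))))

        # candidate text: the full on-topic vocabulary three times over,
        # plus uniform background noise, so the frequent terms are on-topic
        noise = rng.choice(vocab, size=len(block))
        cand_ids = np.concatenate([np.repeat(block, 3), noise])
        rng.shuffle(cand_ids)
        candidate_texts[topic_id] = _doc_text(rng, cand_ids, spec)

    for j in range(spec.n_background_docs):
        doc_id = f"BG-{j + 1:05d}"
        length = max(1, rng.poisson(spec.doc_length_mean))
        token_ids = rng.choice(vocab, size=length)
        documents.append((doc_id, _doc_text(rng, token_ids, spec)))

    return SyntheticBenchmark(documents, topics, Qrels(judgments),
                              candidate_texts, spec)


def write_benchmark(benchmark: SyntheticBenchmark, directory: str | Path) -> None:
    """Write corpus/, topics.tsv, qrels.txt and candidates/ under ``directory``.

    The formats are exactly the ones the indexing, retrieval, expansion and
    evaluation readers consume, so a written benchmark can be read back.
    """
    directory = Path(directory)
    corpus = directory / "corpus"
    candidates = directory / "candidates"
    corpus.mkdir(parents=True, exist_ok=True)
    candidates.mkdir(parents=True, exist_ok=True)
    for doc_id, text in benchmark.documents:
        (corpus / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    with open(directory / "topics.tsv", "w", encoding="utf-8") as fh:
        for topic_id, text in benchmark.topics:
            fh.write(f"{topic_id}\t{text}\n")
    write_qrels(benchmark.qrels, directory / "qrels.txt")
    for topic_id, text in benchmark.candidate_texts.items():
        (candidates / f"{topic_id}.txt").write_text(text, encoding="utf-8")
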