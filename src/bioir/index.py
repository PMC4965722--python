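"""Inverted index over a preprocessed document collection.

The index stores exactly the statistics the downstream ranking and feedback
models need: per-term postings with within-document frequencies (tf), document
frequencies (df), collection frequencies (cf), per-document lengths measured
after stopword removal and stemming, and the collection size N. Persistence is
a flat JSON-lines file so an index survives a save/load round-trip exactly.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .preprocess import PipelineConfig, preprocess

__all__ = [
    "Posting",
    "DocumentRecord",
    "TermStats",
    "InvertedIndex",
    "build_index",
    "read_corpus_dir",
    "read_trec_corpus",
]


@dataclass(frozen=True)
class Posting:
    doc_id: str
    tf: int


@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    term_count: int  # |d| after preprocessing


@dataclass(frozen=True)
class TermStats:
    """df/cf/idf for one term; ``df == 0`` represents an unseen term."""

    term: str
    df: int
    cf: int
    idf: float


@dataclass
class InvertedIndex:
    postings: dict[str, list[Posting]] = field(default_factory=dict)
    doc_table: dict[str, DocumentRecord] = field(default_factory=dict)
    # per-document term frequency vectors, needed by feedback-based expansion
    doc_vectors: dict[str, dict[str, int]] = field(default_factory=dict)
    total_terms: int = 0

    @property
    def n_docs(self) -> int:
        return len(self.doc_table)

    @property
    def vocabulary(self) -> Iterable[str]:
        return self.postings.keys()

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def cf(self, term: str) -> int:
        return sum(p.tf for p in self.postings.get(term, ()))

    def doc_length(self, doc_id: str) -> int:
        return self.doc_table[doc_id].term_count

    def doc_vector(self, doc_id: str) -> dict[str, int]:
        return self.doc_vectors[doc_id]

    def collection_prob(self, term: str) -> float:
        """Maximum-likelihood collection language model P(w|C)."""
        return self.cf(term) / self.total_terms if self.total_terms else 0.0

    def lookup(self, term: str) -> tuple[TermStats, list[Posting]]:
        """Term statistics plus postings; absent terms yield df=0, idf=0."""
        plist = self.postings.get(term, [])
        df = len(plist)
        cf = sum(p.tf for p in plist)
        idf = math.log(self.n_docs / df) if df else 0.0
        return TermStats(term, df, cf, idf), list(plist)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"kind": "header", "total_terms": self.total_terms}) + "\n")
            for doc_id in sorted(self.doc_table):
                rec = self.doc_table[doc_id]
                fh.write(json.dumps({
                    "kind": "doc",
                    "doc_id": doc_id,
                    "term_count": rec.term_count,
                    "vector": self.doc_vectors[doc_id],
                }, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        index = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                if rec["kind"] == "header":
                    index.total_terms = rec["total_terms"]
                else:
                    index._add_document(rec["doc_id"], {t: int(c) for t, c in rec["vector"].items()},
                                        term_count=rec["term_count"])
        return index

    # -- construction --------------------------------------------------------

    def _add_document(self, doc_id: str, vector: dict[str, int], term_count: int | None = None) -> None:
        if doc_id in self.doc_table:
            raise ValueError(f"duplicate doc_id {doc_id!r} in collection")
        length = sum(vector.values())
        if term_count is not None and term_count != length:
            raise ValueError(f"inconsistent term_count for {doc_id!r}")
        self.doc_table[doc_id] = DocumentRecord(doc_id, length)
        self.doc_vectors[doc_id] = dict(vector)
        for term, tf in vector.items():
            self.postings.setdefault(term, []).append(Posting(doc_id, tf))

    def _finalize(self) -> None:
        for term in self.postings:
            self.postings[term].sort(key=lambda p: p.doc_id)
        self.total_terms = sum(r.term_count for r in self.doc_table.values())


def build_index(documents: Iterable[tuple[str, str]],
                config: PipelineConfig | None = None) -> InvertedIndex:
    """Preprocess and index a collection of ``(doc_id, raw_text)`` pairs.

    Duplicate doc_ids and empty collections are rejected. Postings are sorted
    by doc_id so rebuilding from the same input is deterministic.
    """
    if config is None:
        config = PipelineConfig()
    index = InvertedIndex()
    for doc_id, raw_text in documents:
        terms = preprocess(raw_text, config)
        index._add_document(doc_id, dict(Counter(terms)))
    if not index.doc_table:
        raise ValueError("cannot index an empty collection")
    index._finalize()
    return index


# -- corpus readers ----------------------------------------------------------

def read_corpus_dir(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(doc_id, raw_text)`` from a directory of *.txt / *.html files.

    The file stem is the document identifier.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix in (".txt", ".html"))
    if not files:
        raise ValueError(f"no .txt/.html documents found in {path}")
    for p in files:
        yield p.stem, p.read_text(encoding="utf-8")


_DOC_RE = re.compile(r"<DOC>(.*?)</DOC>", re.S)
_DOCNO_RE = re.compile(r"<DOCNO>\s*(.*?)\s*</DOCNO>", re.S)


def read_trec_corpus(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield documents from a single TREC-style ``<DOC>/<DOCNO>`` file."""
    text = Path(path).read_text(encoding="utf-8")
    for match in _DOC_RE.finditer(text):
        body = match.group(1)
        docno = _DOCNO_RE.search(body)
        if docno is None:
            raise ValueError("document without <DOCNO> in TREC corpus file")
        yield docno.group(1), _DOCNO_RE.sub("", body)
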