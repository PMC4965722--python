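"""TREC run / qrels I/O and Mean Average Precision evaluation.

Average Precision for a topic with R judged-relevant documents and a ranked
list d_1..d_n (cut off at rank ``cutoff``) is

    AP = (1/R) * sum over relevant d_k with k <= cutoff of  (# relevant in top k) / k

MAP is the arithmetic mean of AP over topics that have at least one judged
relevant document; topics without judgments are excluded from the mean, the
standard trec-eval convention. A document judged with grade > 0 is relevant;
unjudged documents are non-relevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .retrieval import Run, RunEntry

__all__ = [
    "Qrels",
    "EvalResult",
    "read_run",
    "write_run",
    "read_qrels",
    "write_qrels",
    "average_precision",
    "mean_average_precision",
    "percent_improvement",
]

logger = logging.getLogger(__name__)


@dataclass
class Qrels:
    """Relevance judgments: topic_id -> doc_id -> integer grade (>= 0)."""

    judgments: dict[str, dict[str, int]]

    def topics(self) -> list[str]:
        return list(self.judgments)

    def relevant_docs(self, topic_id: str) -> set[str]:
        return {d for d, g in self.judgments.get(topic_id, {}).items() if g > 0}


@dataclass(frozen=True)
class EvalResult:
    per_topic_ap: dict[str, float]
    map: float
    evaluated_topic_count: int
    skipped_topics: tuple[str, ...] = ()


# -- TREC formats ------------------------------------------------------------

def write_run(run: Run, path: str | Path) -> None:
    """Write the six-column TREC format: ``topic Q0 doc rank score runid``.

    Scores are serialised with fixed six-decimal precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for entry in run.all_entries():
            fh.write(f"{entry.topic_id} Q0 {entry.doc_id} {entry.rank} "
                     f"{entry.score:.6f} {entry.run_id}\n")


def read_run(path: str | Path) -> Run:
    """Parse a TREC run file, validating ranks and score monotonicity."""
    entries: dict[str, list[RunEntry]] = {}
    run_id = "run"
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        topic_id, _q0, doc_id, rank_s, score_s, run_id = fields
        try:
            rank, score = int(rank_s), float(score_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad rank/score") from exc
        entries.setdefault(topic_id, []).append(
            RunEntry(topic_id, doc_id, rank, score, run_id))
    run = Run(run_id, entries)
    run.validate()
    return run


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for topic_id in qrels.judgments:
            for doc_id, grade in qrels.judgments[topic_id].items():
                fh.write(f"{topic_id} 0 {doc_id} {grade}\n")


def read_qrels(path: str | Path) -> Qrels:
    """Parse four-column qrels ``topic 0 doc grade``; duplicate lines: last wins."""
    judgments: dict[str, dict[str, int]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        topic_id, _iter, doc_id, grade_s = fields
        try:
            grade = int(grade_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad relevance grade") from exc
        if grade < 0:
            raise ValueError(f"{path}:{lineno}: negative relevance grade")
        topic = judgments.setdefault(topic_id, {})
        if doc_id in topic:
            logger.warning("%s:%d: duplicate judgment for (%s, %s); last wins",
                           path, lineno, topic_id, doc_id)
        topic[doc_id] = grade
    return Qrels(judgments)


# -- metrics -----------------------------------------------------------------

def average_precision(ranked_docs: Sequence[str], relevant: Iterable[str],
                      cutoff: int = 1000) -> float:
    """AP of one ranked list against a set of relevant doc_ids."""
    relevant = set(relevant)
    if not relevant:
        raise ValueError("average_precision needs at least one relevant document")
    hits = 0
    total = 0.0
    for k, doc_id in enumerate(ranked_docs[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            total += hits / k
    return total / len(relevant)


def mean_average_precision(run: Run, qrels: Qrels, cutoff: int = 1000) -> EvalResult:
    """MAP over the topics of ``qrels`` that have judged relevant documents.

    Topics present in the qrels but with no relevant document, and topics the
    run never retrieved for, are reported in ``skipped_topics``.
    """
    per_topic: dict[str, float] = {}
    skipped: list[str] = []
    for topic_id in qrels.topics():
        relevant = qrels.relevant_docs(topic_id)
        if not relevant:
            skipped.append(topic_id)
            continue
        ranked = [e.doc_id for e in run.for_topic(topic_id)]
        per_topic[topic_id] = average_precision(ranked, relevant, cutoff) if ranked else 0.0
    if not per_topic:
        raise ValueError("no topic with judged relevant documents to evaluate")
    if skipped:
        logger.info("excluded %d topic(s) without relevant judgments", len(skipped))
    map_value = sum(per_topic.values()) / len(per_topic)
    return EvalResult(per_topic, map_value, len(per_topic), tuple(skipped))


def percent_improvement(map_new: float, map_ref: float) -> float:
    """Relative improvement 100 * (new - ref) / ref, rounded to 2 decimals."""
    if map_ref <= 0:
        raise ValueError("reference MAP must be positive")
    return round(100.0 * (map_new - map_ref) / map_ref, 2)
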