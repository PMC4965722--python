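"""Linear score fusion of two retrieval runs with an alpha sweep.

Two runs are merged per topic by the convex combination

    fused(d) = alpha * score1(d) + (1 - alpha) * score2(d)

over the union of their document lists, a missing score counting as zero
(the CombSUM convention). Because the two source runs typically live on
different score scales (raw TF-IDF sums versus interpolated feedback
scores), scores are min-max normalised per topic to [0, 1] before combining
by default; raw-score fusion is kept as an option for sensitivity checks.

``sweep_alpha`` evaluates document MAP for every alpha on a grid (default
0.1, 0.2, ..., 0.9) and returns the best setting, preferring the smallest
alpha on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import Qrels, mean_average_precision
from .retrieval import Run, RunEntry

__all__ = [
    "FusionConfig",
    "FusedRun",
    "SweepResult",
    "normalize_run",
    "linear_combine",
    "sweep_alpha",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class FusionConfig:
    alpha: float = 0.5
    normalization: str = "minmax"  # or "none"
    count: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.normalization not in ("minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class FusedRun(Run):
    """A fused run remembering its two sources and the alpha used."""

    source_run_ids: tuple[str, str] = ("", "")
    alpha: float = 0.5


@dataclass(frozen=True)
class SweepResult:
    best_alpha: float
    best_run: FusedRun
    table: tuple[tuple[float, float], ...]  # (alpha, MAP) rows


def normalize_run(run: Run) -> Run:
    """Per-topic min-max mapping of scores to [0, 1]; ranking unchanged.

    When all scores of a topic are equal they all map to 1.0.
    """
    out = Run(run.run_id)
    for topic_id in run.topics():
        entries = run.for_topic(topic_id)
        if not entries:
            out.add_topic(topic_id, [])
            continue
        scores = [e.score for e in entries]
        lo, hi = min(scores), max(scores)
        span = hi - lo
        out.add_topic(topic_id, [
            RunEntry(e.topic_id, e.doc_id, e.rank,
                     (e.score - lo) / span if span else 1.0, e.run_id)
            for e in entries
        ])
    return out


def linear_combine(run1: Run, run2: Run,
                   config: FusionConfig | None = None,
                   run_id: str | None = None) -> FusedRun:
    """Fuse two runs; topic universe is the union of both runs' topics."""
    if config is None:
        config = FusionConfig()
    if config.normalization == "minmax":
        run1, run2 = normalize_run(run1), normalize_run(run2)
    if run_id is None:
        run_id = f"fuse_{run1.run_id}_{run2.run_id}_a{config.alpha:g}"
    fused = FusedRun(run_id, source_run_ids=(run1.run_id, run2.run_id),
                     alpha=config.alpha)
    topics = list(dict.fromkeys(list(run1.topics()) + list(run2.topics())))
    for topic_id in topics:
        s1 = {e.doc_id: e.score for e in run1.for_topic(topic_id)}
        s2 = {e.doc_id: e.score for e in run2.for_topic(topic_id)}
        union = set(s1) | set(s2)
        scores = {d: config.alpha * s1.get(d, 0.0) + (1.0 - config.alpha) * s2.get(d, 0.0)
                  for d in union}
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:config.count]
        fused.add_topic(topic_id, [
            RunEntry(topic_id, doc_id, rank, score, run_id)
            for rank, (doc_id, score) in enumerate(ordered, start=1)
        ])
    return fused


def sweep_alpha(run1: Run, run2: Run, qrels: Qrels,
                grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
                normalization: str = "minmax",
                count: int = 1000) -> SweepResult:
    """Evaluate MAP for each alpha on the grid and return the best fusion.

    Ties go to the smallest alpha (grids are evaluated in the given order,
    which for the default grid is ascending).
    """
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    run_topics = set(run1.topics()) | set(run2.topics())
    if not any(qrels.relevant_docs(t) for t in qrels.topics() if t in run_topics):
        raise ValueError("no judged topic overlaps the runs being fused")
    rows: list[tuple[float, float]] = []
    best_alpha, best_run, best_map = None, None, float("-inf")
    for alpha in grid:
        fused = linear_combine(run1, run2,
                               FusionConfig(alpha, normalization, count))
        result = mean_average_precision(fused, qrels, cutoff=count)
        rows.append((alpha, result.map))
        if result.map > best_map or (result.map == best_map and alpha < best_alpha):
            best_alpha, best_run, best_map = alpha, fused, result.map
    return SweepResult(best_alpha, best_run, tuple(rows))
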