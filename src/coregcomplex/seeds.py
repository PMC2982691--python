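"""Candidate enumeration inside WCCs and seed selection.

Within each WCC, every connected subgraph whose edge count lies between
``lambda_min`` and ``beta_max`` is a candidate complex.  Enumeration is
exhaustive by canonical edge growth (each subgraph produced exactly once)
up to a work budget; beyond the budget it falls back to a beam search over
partial subgraphs ranked by raw coherence.  Candidates are then scored in
every condition, filtered by the score threshold ``alpha`` and by
consistency between score and TF activity in at least ``theta`` conditions,
and near-duplicates (sharing >= ``overlap_frac`` of the smaller node set)
are collapsed keeping the higher-scoring one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

from .data import TFActivityTable
from .scoring import CandidateComplex, ScoringContext, canonical_edge
from .subnetwork import WCC

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "enumerate_candidates",
    "deduplicate_overlap",
    "consistency_count",
    "select_seeds",
]


@dataclass
class SearchParams:
    """Seed-search parameters.

    ``lambda_min``/``beta_max`` bound a candidate's edge count (defaults
    2 and 21: complexes rarely exceed ten members), ``alpha`` is the
    standardized-score threshold (default 1.90), ``theta`` the minimum
    number of conditions in which score degree and TF activity must agree
    (default 2), ``overlap_frac`` the protein-sharing fraction above which
    two candidates count as duplicates (default 0.8), and ``n_random`` the
    null-distribution sample count (default 10 000).
    """

    lambda_min: int = 2
    beta_max: int = 21
    alpha: float = 1.90
    theta: int = 2
    overlap_frac: float = 0.8
    n_random: int = 10_000
    rng_seed: int = 0
    work_budget: int = 2_000_000
    beam_width: int = 5_000
    overlap_denominator: str = "min"  # min | max | jaccard

    def __post_init__(self):
        if not (1 <= self.lambda_min <= self.beta_max):
            raise ValueError("need 1 <= lambda_min <= beta_max")
        if not (0.0 < self.overlap_frac <= 1.0):
            raise ValueError("overlap_frac must be in (0, 1]")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.overlap_denominator not in ("min", "max", "jaccard"):
            raise ValueError(f"unknown overlap denominator {self.overlap_denominator!r}")


# ---------------------------------------------------------------------------
# enumeration


class _BudgetExceeded(Exception):
    pass


def _adjacent(edges: list[tuple[str, str]]):
    """edge index -> indices of edges sharing an endpoint."""
    by_node: dict[str, list[int]] = {}
    for i, (u, v) in enumerate(edges):
        by_node.setdefault(u, []).append(i)
        by_node.setdefault(v, []).append(i)
    adj: list[list[int]] = []
    for i, (u, v) in enumerate(edges):
        adj.append(sorted(set(by_node[u] + by_node[v]) - {i}))
    return adj


def _exhaustive_edge_subgraphs(
    edges: list[tuple[str, str]], lo: int, hi: int, budget: int
) -> Iterator[frozenset[int]]:
    """Yield every connected edge subset with |S| in [lo, hi], once each.

    Canonical growth: subgraphs are rooted at their minimum edge index and
    extended only with higher-indexed frontier edges; the include/skip
    decision sequence for a fixed root is a function of the final subset,
    so no subset is produced twice.  Raises _BudgetExceeded after
    ``budget`` include-expansions.
    """
    adj = _adjacent(edges)
    count = 0

    def rec(
        root: int, S: frozenset[int], ext: tuple[int, ...], forbidden: frozenset[int]
    ) -> Iterator:
        # Skipped ext entries stay forbidden for the whole subtree: for a
        # fixed root the include/skip decisions are then a function of the
        # final subset, so each subset is produced exactly once.
        nonlocal count
        for j, f in enumerate(ext):
            count += 1
            if count > budget:
                raise _BudgetExceeded
            S2 = S | {f}
            if lo <= len(S2) <= hi:
                yield S2
            if len(S2) < hi:
                skipped = forbidden | frozenset(ext[:j])
                known = S2 | skipped | set(ext)
                new = [g for g in adj[f] if g > root and g not in known]
                yield from rec(root, S2, ext[j + 1 :] + tuple(sorted(new)), skipped)

    for root in range(len(edges)):
        S = frozenset([root])
        if lo <= 1:
            yield S
        ext = tuple(g for g in adj[root] if g > root)
        yield from rec(root, S, ext, frozenset())


def _beam_edge_subgraphs(
    edges: list[tuple[str, str]],
    lo: int,
    hi: int,
    beam_width: int,
    rank: Callable[[frozenset[int]], float],
) -> Iterator[frozenset[int]]:
    """Level-synchronous beam search over connected edge subsets."""
    adj = _adjacent(edges)
    level: set[frozenset[int]] = {frozenset([i]) for i in range(len(edges))}
    for size in range(1, hi + 1):
        if not level:
            break
        if len(level) > beam_width:
            level = set(
                sorted(level, key=lambda s: (-rank(s), tuple(sorted(s))))[:beam_width]
            )
        if lo <= size <= hi:
            yield from sorted(level, key=lambda s: tuple(sorted(s)))
        if size == hi:
            break
        nxt: set[frozenset[int]] = set()
        for S in level:
            frontier = set()
            for f in S:
                frontier.update(adj[f])
            for g in frontier - S:
                nxt.add(S | {g})
        level = nxt


def enumerate_candidates(
    wcc: WCC,
    lambda_min: int = 2,
    beta_max: int = 21,
    work_budget: int = 2_000_000,
    beam_width: int = 5_000,
    rank_fn: Callable[[frozenset[tuple[str, str]]], float] | None = None,
) -> Iterator[CandidateComplex]:
    """Stream connected subgraphs of a WCC with edge count in bounds.

    Exhaustive (each subgraph once) while the work budget holds; if the
    budget is exhausted the WCC is re-searched with a beam of width
    ``beam_width`` ranked by ``rank_fn`` (typically current raw coherence),
    which is logged and no longer exhaustive.
    """
    edges = sorted(canonical_edge(u, v) for u, v in wcc.graph.edges)

    def to_candidate(idx_set: frozenset[int]) -> CandidateComplex:
        es = frozenset(edges[i] for i in idx_set)
        return CandidateComplex(
            nodes=frozenset(n for e in es for n in e), edges=es, tf=wcc.tf
        )

    try:
        produced: list[frozenset[int]] = list(
            _exhaustive_edge_subgraphs(edges, lambda_min, beta_max, work_budget)
        )
        for s in produced:
            yield to_candidate(s)
        return
    except _BudgetExceeded:
        logger.warning(
            "WCC for %s (%d edges) exceeded the enumeration budget; "
            "falling back to beam search (width %d)",
            wcc.tf,
            len(edges),
            beam_width,
        )

    if rank_fn is None:
        def rank(idx_set: frozenset[int]) -> float:
            return float(len({n for i in idx_set for n in edges[i]}))
    else:
        def rank(idx_set: frozenset[int]) -> float:
            return rank_fn(frozenset(edges[i] for i in idx_set))

    for s in _beam_edge_subgraphs(edges, lambda_min, beta_max, beam_width, rank):
        yield to_candidate(s)


# ---------------------------------------------------------------------------
# selection


def _overlap(a: frozenset, b: frozenset, denominator: str) -> float:
    inter = len(a & b)
    if denominator == "min":
        den = min(len(a), len(b))
    elif denominator == "max":
        den = max(len(a), len(b))
    else:
        den = len(a | b)
    return inter / den if den else 0.0


def deduplicate_overlap(
    cands: Iterable[CandidateComplex],
    overlap_frac: float = 0.8,
    scores: Mapping[int, float] | None = None,
    denominator: str = "min",
) -> list[CandidateComplex]:
    """Greedy overlap-based deduplication, best score first.

    A candidate is kept iff its protein overlap with every already-kept
    candidate is below ``overlap_frac``; the overlap denominator defaults
    to the smaller node set, so a subset counts as full overlap.  Ties on
    score break toward the lexicographically smallest sorted node list.
    """

    def score_of(i: int, c: CandidateComplex) -> float:
        if scores is not None:
            return scores[i]
        return c.max_score()

    indexed = sorted(
        enumerate(cands),
        key=lambda ic: (-score_of(*ic), ic[1].sorted_nodes()),
    )
    kept: list[CandidateComplex] = []
    for _, cand in indexed:
        if all(
            _overlap(cand.nodes, k.nodes, denominator) < overlap_frac for k in kept
        ):
            kept.append(cand)
    return kept


def consistency_count(
    scores_by_condition: Mapping[str, float],
    activity: Mapping[str, bool],
    alpha: float,
) -> int:
    """Conditions where score degree agrees with TF activity.

    Agreement means: active and Score >= alpha, or inactive and
    Score < alpha.
    """
    if set(scores_by_condition) != set(activity):
        raise KeyError(
            "scores and activity must cover the same conditions "
            f"(got {sorted(scores_by_condition)} vs {sorted(activity)})"
        )
    count = 0
    for cond, score in scores_by_condition.items():
        active = activity[cond]
        if (active and score >= alpha) or (not active and score < alpha):
            count += 1
    return count


def select_seeds(
    cands: Iterable[CandidateComplex],
    activity_table: TFActivityTable,
    params: SearchParams,
    context: ScoringContext,
) -> list[CandidateComplex]:
    """Score, threshold, consistency-filter and deduplicate candidates.

    Keeps candidates whose best per-condition Score reaches ``alpha`` and
    whose score degree agrees with their TF's activity in at least
    ``theta`` conditions, then collapses overlapping candidates.  Output is
    sorted by descending best Score.
    """
    surviving: list[CandidateComplex] = []
    for cand in cands:
        if cand.tf is None:
            raise ValueError("candidates must carry a TF label for selection")
        context.score_candidate(cand)
        if cand.max_score() < params.alpha:
            continue
        cand.consistency = consistency_count(
            cand.std_score, activity_table.activity_of(cand.tf), params.alpha
        )
        if cand.consistency < params.theta:
            continue
        surviving.append(cand)
    kept = deduplicate_overlap(
        surviving,
        overlap_frac=params.overlap_frac,
        denominator=params.overlap_denominator,
    )
    kept.sort(key=lambda c: (-c.max_score(), c.sorted_nodes()))
    return kept
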