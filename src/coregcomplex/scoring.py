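"""Coherence scoring of candidate complexes.

The score of a candidate complex ``L = (P', E')`` under one condition is
built in three layers:

1. **edge coherence** -- the Pearson correlation between the expression
   profiles of the two coding genes of an interacting protein pair,
   computed over pairwise-complete time points (time points missing in
   either profile are skipped, never imputed).  The correlation is used
   signed and unweighted: no per-gene variance factor enters the edge
   score.
2. **raw score** ``T(L)`` -- the sum of edge coherences over all edges of
   ``L``.  If any member's coding gene is absent from the condition's
   expression data, ``T(L) = 0`` with an explicit no-coverage flag.
3. **standardized score** ``Score(L)`` -- because ``T`` grows with the
   number of edges ``K``, it is standardized against an empirical null:
   sample ``n`` random connected ``K``-edge subgraphs of the PPI network
   (default n = 10 000), score each with ``T``, and report
   ``Score(L) = (T(L) - mean) / std``.

The random subgraphs are grown connected -- a uniform random start edge
followed by uniform random frontier-edge additions -- because candidates
are themselves connected; an unconstrained edge-set null is available via
``null="edge-set"``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .data import ExpressionPanel, PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateComplex",
    "RandomScoreReference",
    "RawScore",
    "DegenerateReferenceError",
    "UndefinedCoherenceError",
    "edge_coherence",
    "raw_score",
    "sample_random_reference",
    "standardized_score",
    "ScoringContext",
    "canonical_edge",
]


class DegenerateReferenceError(ValueError):
    """The null distribution has zero spread; standardization refuses."""

    def __init__(self, K: int, condition: str | None = None):
        self.K = K
        self.condition = condition
        super().__init__(
            f"degenerate score reference for K={K}"
            + (f" under condition {condition!r}" if condition else "")
        )


class UndefinedCoherenceError(ValueError):
    """Fewer than 3 paired observations, or a constant retained profile."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def _nodes_of(edges: Iterable[tuple[str, str]]) -> frozenset[str]:
    return frozenset(n for e in edges for n in e)


def _is_connected_edges(edges: Iterable[tuple[str, str]]) -> bool:
    g = nx.Graph(list(edges))
    return g.number_of_nodes() > 0 and nx.is_connected(g)


@dataclass
class CandidateComplex:
    """A connected protein subgraph with per-condition scores.

    ``raw_T``/``std_score``/``no_coverage`` are filled per condition as
    scoring proceeds; ``std_score`` is reported as 0.0 for a condition
    whose expression data does not cover every member gene (flagged in
    ``no_coverage``).
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    tf: str | None = None
    raw_T: dict = field(default_factory=dict)
    std_score: dict = field(default_factory=dict)
    no_coverage: dict = field(default_factory=dict)
    consistency: int | None = None

    def __post_init__(self):
        self.edges = frozenset(canonical_edge(*e) for e in self.edges)
        endpoints = _nodes_of(self.edges)
        if not endpoints <= self.nodes:
            raise ValueError("edge endpoints must all be candidate members")
        if self.edges and not _is_connected_edges(self.edges):
            raise ValueError("candidate complex must be connected")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def max_score(self) -> float:
        if not self.std_score:
            raise ValueError("candidate has no standardized scores yet")
        return max(self.std_score.values())

    def sorted_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.nodes))

    def __repr__(self) -> str:
        tf = f"tf={self.tf}, " if self.tf else ""
        return (
            f"CandidateComplex({tf}{len(self.nodes)} nodes, "
            f"{len(self.edges)} edges)"
        )


@dataclass
class RandomScoreReference:
    """Null mean/std of T over random connected K-edge subgraphs."""

    edge_count: int
    mean_T: float
    std_T: float
    n_samples: int
    condition: str
    rng_seed: int
    samples: np.ndarray | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.std_T < 0:
            raise ValueError("std_T must be non-negative")

    @property
    def degenerate(self) -> bool:
        return self.std_T == 0.0


class RawScore(float):
    """T(L) with a coverage flag (``covered=False`` forces T = 0)."""

    def __new__(cls, value: float, covered: bool = True):
        obj = super().__new__(cls, value)
        obj.covered = covered
        return obj


# ---------------------------------------------------------------------------
# layer 1: edge coherence


def edge_coherence(profile_i, profile_j) -> float | None:
    """Pearson correlation over pairwise-complete time points.

    Returns ``None`` -- the undefined-coherence signal, distinct from 0 --
    when fewer than 3 paired observations remain or a retained profile is
    constant.
    """
    x = np.asarray(profile_i, dtype=float)
    y = np.asarray(profile_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the same time points")
    mask = np.isfinite(x) & np.isfinite(y)
    if int(mask.sum()) < 3:
        return None
    xs = x[mask]
    ys = y[mask]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    sx = float(np.sqrt(np.dot(xs, xs)))
    sy = float(np.sqrt(np.dot(ys, ys)))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.dot(xs, ys) / (sx * sy))
    return max(-1.0, min(1.0, r))


# ---------------------------------------------------------------------------
# layer 2: raw score


def raw_score(
    cand: CandidateComplex, panel: ExpressionPanel, condition: str
) -> RawScore:
    """T(L): sum of edge coherences under one condition.

    If any member gene lacks a profile in the condition, returns 0 with
    ``covered=False``.  An undefined coherence on a fully covered edge is
    an error naming the edge.
    """
    profiles = {}
    for node in cand.nodes:
        p = panel.profile(node, condition)
        if p is None:
            return RawScore(0.0, covered=False)
        profiles[node] = p
    total = 0.0
    for u, v in cand.edges:
        r = edge_coherence(profiles[u], profiles[v])
        if r is None:
            raise UndefinedCoherenceError(
                f"undefined coherence on covered edge ({u}, {v}) "
                f"under condition {condition!r}"
            )
        total += r
    return RawScore(total, covered=True)


# ---------------------------------------------------------------------------
# layer 3: randomization null


def _edge_values(
    ppi: PPINetwork, panel: ExpressionPanel, condition: str
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Per-edge coherence array aligned to a sorted edge list.

    Returns (edges, value-per-edge, node-covered flag per edge).  Edges
    with an uncovered endpoint get value NaN and covered=False; an
    undefined coherence on a covered pair raises.
    """
    edges = sorted(ppi.edges())
    prof = {}
    for u, v in edges:
        for n in (u, v):
            if n not in prof:
                prof[n] = panel.profile(ppi.gene_of(n), condition)
    vals = np.empty(len(edges))
    covered = np.empty(len(edges), dtype=bool)
    for i, (u, v) in enumerate(edges):
        if prof[u] is None or prof[v] is None:
            vals[i] = np.nan
            covered[i] = False
            continue
        r = edge_coherence(prof[u], prof[v])
        if r is None:
            raise UndefinedCoherenceError(
                f"undefined coherence on covered PPI edge ({u}, {v}) "
                f"under condition {condition!r}"
            )
        vals[i] = r
        covered[i] = True
    return edges, vals, covered


def _sample_connected_edge_sets(
    ppi: PPINetwork, K: int, n: int, rng: np.random.Generator
) -> list[list[int]]:
    """Grow ``n`` connected K-edge subgraphs; returns edge-index lists.

    Each sample starts from a uniform random edge of a component holding at
    least K edges and repeatedly adds a uniform random frontier edge.
    """
    edges = sorted(ppi.edges())
    eidx = {e: i for i, e in enumerate(edges)}
    inc: dict[str, list[int]] = {}
    for i, (u, v) in enumerate(edges):
        inc.setdefault(u, []).append(i)
        inc.setdefault(v, []).append(i)
    # restrict start edges to components that can host K edges
    eligible = []
    for comp in nx.connected_components(ppi.graph):
        sub = ppi.graph.subgraph(comp)
        if sub.number_of_edges() >= K:
            eligible.extend(
                eidx[canonical_edge(u, v)] for u, v in sub.edges
            )
    if not eligible:
        raise ValueError(f"PPI network has no connected subgraph with K={K} edges")
    eligible.sort()
    samples: list[list[int]] = []
    for _ in range(n):
        start = eligible[int(rng.integers(len(eligible)))]
        chosen = {start}
        frontier: list[int] = []
        in_frontier = {start}
        for node in edges[start]:
            for j in inc[node]:
                if j not in in_frontier:
                    frontier.append(j)
                    in_frontier.add(j)
        while len(chosen) < K:
            # uniform over distinct frontier edges; stale entries rejected
            pos = int(rng.integers(len(frontier)))
            j = frontier[pos]
            frontier[pos] = frontier[-1]
            frontier.pop()
            if j in chosen:
                continue
            chosen.add(j)
            for node in edges[j]:
                for k2 in inc[node]:
                    if k2 not in in_frontier:
                        frontier.append(k2)
                        in_frontier.add(k2)
        samples.append(sorted(chosen))
    return samples


def sample_random_reference(
    ppi: PPINetwork,
    K: int,
    panel: ExpressionPanel,
    condition: str,
    n: int = 10_000,
    seed: int = 0,
    null: str = "connected",
    keep_samples: bool = False,
    _edge_cache: tuple | None = None,
) -> RandomScoreReference:
    """Empirical null of T over ``n`` random K-edge subgraphs.

    ``null="connected"`` (default) grows connected subgraphs; ``"edge-set"``
    draws K distinct edges without a connectivity constraint.  Deterministic
    given ``seed``.
    """
    if n < 2:
        raise ValueError("need n >= 2 null samples")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    edges, vals, covered = (
        _edge_cache
        if _edge_cache is not None
        else _edge_values(ppi, panel, condition)
    )
    if null == "connected":
        index_sets = _sample_connected_edge_sets(ppi, K, n, rng)
    elif null == "edge-set":
        if len(edges) < K:
            raise ValueError(f"PPI network has fewer than K={K} edges")
        m = len(edges)
        index_sets = [sorted(rng.choice(m, size=K, replace=False)) for _ in range(n)]
    else:
        raise ValueError(f"unknown null type {null!r}")
    ts = np.empty(n)
    for i, idxs in enumerate(index_sets):
        idxs = np.asarray(idxs)
        # a subgraph touching an uncovered gene scores 0, like candidates
        ts[i] = 0.0 if not covered[idxs].all() else float(vals[idxs].sum())
    ref = RandomScoreReference(
        edge_count=K,
        mean_T=float(ts.mean()),
        std_T=float(ts.std(ddof=0)),
        n_samples=n,
        condition=condition,
        rng_seed=seed,
        samples=ts if keep_samples else None,
    )
    if ref.degenerate:
        logger.warning("degenerate null reference for K=%d (%s)", K, condition)
    return ref


def standardized_score(raw_T: float, ref: RandomScoreReference) -> float:
    """Score(L) = (T(L) - mean) / std against the K-edge null."""
    if ref.degenerate:
        raise DegenerateReferenceError(ref.edge_count, ref.condition)
    return (float(raw_T) - ref.mean_T) / ref.std_T


# ---------------------------------------------------------------------------
# shared scoring context


def _derive_seed(base_seed: int, condition: str, K: int) -> int:
    """Stable per-(condition, K) stream seed below 2**31."""
    return zlib.crc32(f"{base_seed}:{condition}:{K}".encode()) & 0x7FFFFFFF


class ScoringContext:
    """Caches edge coherences and per-(condition, K) null references.

    One context is shared by candidate scoring, seed selection and the
    annealing extension so that every stage standardizes against the same
    nulls.  References are keyed by (condition, K) with a seed derived
    deterministically from ``base_seed``; the persisted cache is also keyed
    by the PPI content hash.
    """

    def __init__(
        self,
        ppi: PPINetwork,
        panel: ExpressionPanel,
        n_samples: int = 10_000,
        base_seed: int = 0,
        null: str = "connected",
    ):
        self.ppi = ppi
        self.panel = panel
        self.n_samples = n_samples
        self.base_seed = base_seed
        self.null = null
        self._refs: dict[tuple[str, int], RandomScoreReference] = {}
        self._edge_cache: dict[str, tuple] = {}
        self._edge_val: dict[str, dict[tuple[str, str], float]] = {}
        self._edge_cov: dict[str, dict[tuple[str, str], bool]] = {}

    # -- caches -----------------------------------------------------------

    def _cond_cache(self, condition: str):
        if condition not in self._edge_cache:
            cache = _edge_values(self.ppi, self.panel, condition)
            self._edge_cache[condition] = cache
            edges, vals, covered = cache
            self._edge_val[condition] = dict(zip(edges, vals))
            self._edge_cov[condition] = dict(zip(edges, covered))
        return self._edge_cache[condition]

    def reference(self, K: int, condition: str) -> RandomScoreReference:
        key = (condition, K)
        if key not in self._refs:
            self._refs[key] = sample_random_reference(
                self.ppi,
                K,
                self.panel,
                condition,
                n=self.n_samples,
                seed=_derive_seed(self.base_seed, condition, K),
                null=self.null,
                _edge_cache=self._cond_cache(condition),
            )
        return self._refs[key]

    # -- scoring ----------------------------------------------------------

    def raw_score_edges(
        self, edges: Iterable[tuple[str, str]], condition: str
    ) -> RawScore:
        """T over an explicit edge set, via the per-condition edge cache."""
        self._cond_cache(condition)
        cov = self._edge_cov[condition]
        val = self._edge_val[condition]
        total = 0.0
        for e in edges:
            e = canonical_edge(*e)
            if not cov[e]:
                return RawScore(0.0, covered=False)
            total += val[e]
        return RawScore(total, covered=True)

    def score_edges(self, edges: Iterable[tuple[str, str]], condition: str) -> float:
        """Standardized score of an edge set (0.0 when not covered)."""
        edges = list(edges)
        t = self.raw_score_edges(edges, condition)
        if not t.covered:
            return 0.0
        return standardized_score(t, self.reference(len(edges), condition))

    def score_candidate(self, cand: CandidateComplex) -> CandidateComplex:
        """Fill raw_T / std_score / no_coverage for every condition."""
        for cond in self.panel.conditions:
            if cond in cand.std_score:
                continue
            t = self.raw_score_edges(cand.edges, cond)
            cand.raw_T[cond] = float(t)
            cand.no_coverage[cond] = not t.covered
            cand.std_score[cond] = (
                0.0
                if not t.covered
                else standardized_score(t, self.reference(cand.n_edges, cond))
            )
        return cand

    # -- persistence ------------------------------------------------------

    def save_references(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write("ppi_hash\tcondition\tK\tn\tseed\tmean\tstd\n")
            h = self.ppi.content_hash()
            for (cond, K), ref in sorted(self._refs.items()):
                fh.write(
                    f"{h}\t{cond}\t{K}\t{ref.n_samples}\t{ref.rng_seed}\t"
                    f"{ref.mean_T!r}\t{ref.std_T!r}\n"
                )

    def load_references(self, path: str | Path) -> int:
        """Load cached references matching this PPI's content hash."""
        n_loaded = 0
        h = self.ppi.content_hash()
        with open(path, "rt") as fh:
            header = fh.readline()
            for ln in fh:
                cells = ln.rstrip("\n").split("\t")
                if len(cells) != 7 or cells[0] != h:
                    continue
                cond, K = cells[1], int(cells[2])
                self._refs[(cond, K)] = RandomScoreReference(
                    edge_count=K,
                    mean_T=float(cells[5]),
                    std_T=float(cells[6]),
                    n_samples=int(cells[3]),
                    condition=cond,
                    rng_seed=int(cells[4]),
                )
                n_loaded += 1
        return n_loaded
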