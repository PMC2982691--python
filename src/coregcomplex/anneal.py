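"""Seed extension in the global PPI network by simulated annealing.

Starting from a seed complex, each iteration picks a uniform random vertex
``v`` of the current graph and a uniform random PPI edge ``e`` incident to
``v``.  If ``e`` is already present, it is deleted -- but only when the
graph stays connected without it and ``e`` is not one of the protected
seed edges (re-selecting a protected or bridge edge is a null move);
otherwise ``e`` is added, possibly introducing a new vertex.  The move is
accepted when it raises the standardized score, and otherwise with the
Metropolis probability ``exp(delta / T_i)`` under a geometric temperature
schedule from ``t_start`` down to ``t_end`` over ``n_iter`` iterations.
Seed edges are never removed, so the seed survives inside the result.

When a seed is active under several conditions, the per-condition
extension results are intersected: only proteins added under every
condition are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import PPINetwork
from .scoring import CandidateComplex, ScoringContext, canonical_edge

logger = logging.getLogger(__name__)

__all__ = ["AnnealParams", "ExtendedComplex", "anneal", "intersect_extensions"]


@dataclass
class AnnealParams:
    """Annealing schedule: start/end temperature and iteration count.

    The default starts near the end temperature: seeds enter the extension
    already locally optimal under the core-neighbour strategy, so a hot
    start only floods them with weak members that the cooled phase cannot
    shed.  Raise ``t_start`` (e.g. to 1 or 2) to escape local optima at
    the cost of more exploratory acceptance.
    """

    t_start: float = 0.05
    t_end: float = 0.01
    n_iter: int = 3000
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.t_end <= self.t_start):
            raise ValueError("need 0 < t_end <= t_start")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class ExtendedComplex:
    """Result of extending one seed under one condition (or intersected)."""

    seed: CandidateComplex
    result: CandidateComplex
    added_nodes: frozenset[str]
    condition: str | None = None
    score_trace: list = field(default_factory=list, repr=False)

    def final_score(self) -> float:
        if self.score_trace:
            return self.score_trace[-1][2]
        raise ValueError("no trace recorded")

    def write_trace(self, path) -> None:
        """Trace TSV (iteration, temperature, score, edges)."""
        with open(path, "wt") as fh:
            fh.write("iteration\ttemperature\tscore\tedges\n")
            for it, temp, score, n_edges in self.score_trace:
                fh.write(f"{it}\t{temp!r}\t{score!r}\t{n_edges}\n")


def _still_connected_without(
    edges: set[tuple[str, str]], e: tuple[str, str]
) -> bool:
    g = nx.Graph(list(edges - {e}))
    return g.number_of_nodes() > 0 and nx.is_connected(g)


def anneal(
    seed: CandidateComplex,
    ppi: PPINetwork,
    context: ScoringContext,
    condition: str,
    params: AnnealParams | None = None,
    validate: bool = False,
) -> ExtendedComplex:
    """Extend a seed under one condition by simulated annealing.

    Deterministic given ``params.rng_seed``.  ``validate=True`` asserts the
    invariants (seed edges protected, connectivity) after every iteration.
    Null references for edge counts first met during the run are built
    lazily from the context's seeded per-(condition, K) streams.
    """
    if params is None:
        params = AnnealParams()
    missing = seed.nodes - ppi.proteins
    if missing:
        raise ValueError(f"seed node(s) absent from PPI: {sorted(missing)}")
    protected = frozenset(canonical_edge(*e) for e in seed.edges)
    cur_edges: set[tuple[str, str]] = set(protected)
    score_rs = context.score_edges(cur_edges, condition)
    rng = np.random.default_rng(params.rng_seed)
    ratio = params.t_end / params.t_start
    trace: list[tuple[int, float, float, int]] = []
    cur_nodes = sorted({n for e in cur_edges for n in e})
    for i in range(1, params.n_iter + 1):
        t_i = params.t_start * ratio ** (i / params.n_iter)
        v = cur_nodes[int(rng.integers(len(cur_nodes)))]
        incident = ppi.incident_edges(v)
        if not incident:
            trace.append((i, t_i, float(score_rs), len(cur_edges)))
            continue
        e = incident[int(rng.integers(len(incident)))]
        if e in cur_edges:
            if e not in protected and _still_connected_without(cur_edges, e):
                try_edges = cur_edges - {e}
            else:
                # protected or bridge edge re-selected: null move
                trace.append((i, t_i, float(score_rs), len(cur_edges)))
                continue
        else:
            try_edges = cur_edges | {e}
        score_try = context.score_edges(try_edges, condition)
        delta = score_try - score_rs
        if delta > 0 or rng.random() < math.exp(delta / t_i):
            cur_edges = try_edges
            score_rs = score_try
            cur_nodes = sorted({n for ed in cur_edges for n in ed})
            if validate:
                assert protected <= cur_edges, "seed edge lost during annealing"
                g = nx.Graph(list(cur_edges))
                assert nx.is_connected(g), "annealing graph disconnected"
        trace.append((i, t_i, float(score_rs), len(cur_edges)))
    result_nodes = frozenset(n for e in cur_edges for n in e)
    result = CandidateComplex(
        nodes=result_nodes, edges=frozenset(cur_edges), tf=seed.tf
    )
    context.score_candidate(result)
    return ExtendedComplex(
        seed=seed,
        result=result,
        added_nodes=result_nodes - seed.nodes,
        condition=condition,
        score_trace=trace,
    )


def intersect_extensions(
    results: list[ExtendedComplex], ppi: PPINetwork
) -> ExtendedComplex:
    """Overlap of per-condition extensions of the same seed.

    Keeps only proteins added under every condition; the result graph is
    the seed plus the PPI edges induced over seed members and the shared
    additions.
    """
    if not results:
        raise ValueError("need at least one extension result")
    seed = results[0].seed
    for r in results[1:]:
        if r.seed.nodes != seed.nodes or r.seed.edges != seed.edges:
            raise ValueError("extensions to intersect must share the same seed")
    if len(results) == 1:
        return results[0]
    added = frozenset.intersection(*(r.added_nodes for r in results))
    nodes = seed.nodes | added
    induced = ppi.induced(nodes)
    edges = frozenset(
        canonical_edge(u, v) for u, v in induced.edges
    ) | seed.edges
    result = CandidateComplex(nodes=nodes, edges=edges, tf=seed.tf)
    return ExtendedComplex(
        seed=seed,
        result=result,
        added_nodes=added,
        condition=None,
        score_trace=[],
    )
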