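"""Core in-memory containers for the three integrated data sources.

The framework integrates, under a set of biological conditions,

* transcription-regulation (TR) interactions: which transcription factor
  (TF) regulates which gene,
* gene-expression (GE) time courses: one genes x time-points matrix per
  condition, with missing measurements allowed, and
* an undirected protein-protein interaction (PPI) network, with a map from
  each protein to its coding gene.

Everything is keyed by systematic gene ID; protein IDs default to the
identity map onto gene IDs when no explicit map is supplied.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionPanel",
    "RegulatoryNetwork",
    "PPINetwork",
    "TFActivityTable",
]


class ExpressionPanel:
    """Per-condition gene x time-point expression matrices.

    Parameters
    ----------
    frames
        Mapping from condition label to a DataFrame indexed by gene ID with
        one column per time point.  ``NaN`` entries mark missing
        measurements; they are never imputed.

    A queried ``(gene, condition)`` either returns a profile or ``None``
    (the explicit "absent" marker) -- absence is never silently coerced to
    zeros.  A gene with no observed value at all in a condition counts as
    absent there.
    """

    def __init__(self, frames: Mapping[str, pd.DataFrame]):
        if not frames:
            raise ValueError("expression panel needs at least one condition")
        self._frames: dict[str, pd.DataFrame] = {}
        for cond, df in frames.items():
            if df.shape[1] < 2:
                raise ValueError(
                    f"condition {cond!r} has {df.shape[1]} time points; need >= 2"
                )
            if df.index.has_duplicates:
                dup = df.index[df.index.duplicated()][0]
                raise ValueError(f"duplicate gene ID {dup!r} in condition {cond!r}")
            self._frames[cond] = df.astype(float)
        self.conditions: list[str] = list(self._frames)

    # -- access -----------------------------------------------------------

    def frame(self, condition: str) -> pd.DataFrame:
        """The full matrix for one condition (treat as read-only)."""
        return self._frames[condition]

    def genes(self, condition: str) -> pd.Index:
        return self._frames[condition].index

    def has_profile(self, gene: str, condition: str) -> bool:
        df = self._frames[condition]
        if gene not in df.index:
            return False
        return bool(np.isfinite(df.loc[gene].to_numpy()).any())

    def profile(self, gene: str, condition: str):
        """Expression profile as a float array (NaN = missing), or None."""
        if not self.has_profile(gene, condition):
            return None
        return self._frames[condition].loc[gene].to_numpy(dtype=float)

    def covers(self, gene: str) -> bool:
        """True if the gene has a profile in at least one condition."""
        return any(self.has_profile(gene, c) for c in self.conditions)

    def n_timepoints(self, condition: str) -> int:
        return self._frames[condition].shape[1]

    def __eq__(self, other) -> bool:  # NaN-aware, used by round-trip tests
        if not isinstance(other, ExpressionPanel):
            return NotImplemented
        if self.conditions != other.conditions:
            return False
        for c in self.conditions:
            a, b = self._frames[c], other._frames[c]
            if not a.index.equals(b.index) or a.shape != b.shape:
                return False
            av, bv = a.to_numpy(), b.to_numpy()
            if not ((av == bv) | (np.isnan(av) & np.isnan(bv))).all():
                return False
        return True

    def __repr__(self) -> str:
        shapes = ", ".join(
            f"{c}: {f.shape[0]}x{f.shape[1]}" for c, f in self._frames.items()
        )
        return f"ExpressionPanel({shapes})"


@dataclass(frozen=True)
class RegulatoryNetwork:
    """TF -> target-gene interaction set (the TR data)."""

    tfs: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        stray = {tf for tf, _ in self.edges} - self.tfs
        if stray:
            raise ValueError(f"edges reference undeclared TFs: {sorted(stray)[:5]}")

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        edges = frozenset((tf, tg) for tf, tg in pairs)
        return cls(tfs=frozenset(tf for tf, _ in edges), edges=edges)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(tg for t, tg in self.edges if t == tf)

    def is_target(self, tf: str, gene: str) -> bool:
        return (tf, gene) in self.edges

    def __len__(self) -> int:
        return len(self.edges)


class PPINetwork:
    """Undirected protein-protein interaction network.

    Self-loops are dropped (a protein cannot be its own complex partner
    under the edge-wise score) and duplicate edges are collapsed.  The
    ``coding_gene_of`` map resolves each protein to its coding gene; the
    default is the identity map.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        coding_gene_of: Mapping[str, str] | None = None,
        proteins: Iterable[str] | None = None,
    ):
        g = nx.Graph()
        if proteins is not None:
            g.add_nodes_from(proteins)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.info("dropped %d self-loop(s) from PPI input", n_loops)
        self.graph: nx.Graph = g
        self._gene_of = dict(coding_gene_of) if coding_gene_of is not None else None
        self.n_self_loops_dropped = n_loops
        self._incident: dict[str, tuple[tuple[str, str], ...]] = {}

    # -- basic views ------------------------------------------------------

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        """Edges in canonical (sorted-pair) form."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def gene_of(self, protein: str) -> str:
        if self._gene_of is None:
            return protein
        return self._gene_of.get(protein, protein)

    def is_mapped(self, protein: str) -> bool:
        return self._gene_of is None or protein in self._gene_of

    def incident_edges(self, protein: str) -> tuple[tuple[str, str], ...]:
        """Sorted canonical edges incident to a protein (cached)."""
        cached = self._incident.get(protein)
        if cached is None:
            cached = tuple(
                sorted(tuple(sorted((protein, nb))) for nb in self.graph[protein])
            )
            self._incident[protein] = cached
        return cached

    def induced(self, nodes: Iterable[str]) -> nx.Graph:
        return self.graph.subgraph(set(nodes) & set(self.graph.nodes)).copy()

    def subset(self, keep: Iterable[str]) -> "PPINetwork":
        keep = set(keep)
        edges = [e for e in self.graph.edges if e[0] in keep and e[1] in keep]
        gmap = (
            None
            if self._gene_of is None
            else {p: g for p, g in self._gene_of.items() if p in keep}
        )
        return PPINetwork(edges, coding_gene_of=gmap, proteins=keep)

    def content_hash(self) -> str:
        """Stable digest of the edge set; keys the null-reference cache."""
        payload = "\n".join(f"{u}\t{v}" for u, v in sorted(self.edges()))
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def __repr__(self) -> str:
        return (
            f"PPINetwork({self.graph.number_of_nodes()} proteins, "
            f"{self.graph.number_of_edges()} edges)"
        )


@dataclass
class TFActivityTable:
    """Per-(TF, condition) boolean activity flags.

    Covers exactly the cross product of declared TFs and conditions.
    """

    tfs: frozenset[str]
    conditions: tuple[str, ...]
    flags: dict = field(repr=False)

    def __post_init__(self):
        expected = {(tf, c) for tf in self.tfs for c in self.conditions}
        if set(self.flags) != expected:
            missing = expected - set(self.flags)
            extra = set(self.flags) - expected
            raise ValueError(
                f"activity table must cover TFs x conditions exactly "
                f"(missing {len(missing)}, extraneous {len(extra)})"
            )

    @classmethod
    def from_partial(
        cls,
        tfs: Iterable[str],
        conditions: Iterable[str],
        flags: Mapping[tuple[str, str], bool],
        warn_missing: bool = False,
    ) -> "TFActivityTable":
        tfs = frozenset(tfs)
        conditions = tuple(conditions)
        full = {}
        n_defaulted = 0
        for tf in tfs:
            for c in conditions:
                if (tf, c) in flags:
                    full[(tf, c)] = bool(flags[(tf, c)])
                else:
                    full[(tf, c)] = False
                    n_defaulted += 1
        if n_defaulted and warn_missing:
            logger.warning(
                "%d (TF, condition) pairs absent from activity input; "
                "defaulted to inactive",
                n_defaulted,
            )
        return cls(tfs=tfs, conditions=conditions, flags=full)

    def is_active(self, tf: str, condition: str) -> bool:
        return self.flags[(tf, condition)]

    def active_conditions(self, tf: str) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if self.flags[(tf, c)])

    def active_tfs(self, condition: str) -> frozenset[str]:
        return frozenset(tf for tf in self.tfs if self.flags[(tf, condition)])

    def activity_of(self, tf: str) -> dict[str, bool]:
        return {c: self.flags[(tf, c)] for c in self.conditions}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf, "condition": c, "active": self.flags[(tf, c)]}
            for tf in sorted(self.tfs)
            for c in self.conditions
        ]
        return pd.DataFrame(rows, columns=["tf", "condition", "active"])

    def __len__(self) -> int:
        return len(self.flags)
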