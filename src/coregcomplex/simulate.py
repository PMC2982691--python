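"""Synthetic TR / GE / PPI triples with planted co-regulated complexes.

The generator emulates the structure of the yeast-scale inputs at desk
scale: a few hundred genes, three conditions with unequal time-course
lengths, TF regulons of a few to a few dozen targets, and planted
complexes whose members

* are targets of a shared TF (requirement i),
* are wired into a connected PPI subgraph (requirement ii), and
* share a latent smooth time course in the TF's active conditions, with
  independent per-member noise calibrated so the expected pairwise Pearson
  correlation equals ``within_complex_corr`` (requirement iii).

In TF-inactive conditions planted members express as independent noise,
so their coherence collapses along with the TF's activity.  Optionally
some planted members are withheld from the regulation table (their
expression and PPI wiring stay intact) to exercise the regulation
inference end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionPanel, PPINetwork, RegulatoryNetwork, TFActivityTable

__all__ = ["GeneratorParams", "PlantedComplex", "GroundTruth", "SyntheticData", "generate"]

#: default per-condition time-point counts (longest first, like typical
#: cell-cycle vs shift experiments)
DEFAULT_CONDITIONS: tuple[tuple[str, int], ...] = (("c1", 40), ("c2", 30), ("c3", 14))


@dataclass
class GeneratorParams:
    """Study-condition knobs for the synthetic triple.

    Defaults: 200 genes, 10 TFs, 3 conditions of 40/30/14 time points,
    3 planted complexes of 4--6 members with expected intra-complex
    Pearson 0.8 when their TF is active, background edge probability 0.02
    (mean degree ~4), unit-variance background noise, 2% missing values.
    """

    n_genes: int = 200
    n_tfs: int = 10
    conditions: Sequence[tuple[str, int]] = DEFAULT_CONDITIONS
    n_planted: int = 3
    complex_size_range: tuple[int, int] = (4, 6)
    within_complex_corr: float = 0.8
    background_edge_prob: float = 0.02
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    heldout_tr_per_complex: int = 0
    active_conditions_per_complex: int = 2
    tf_active_shift: float = 2.0
    intra_complex_extra_edge_prob: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.complex_size_range
        if lo < 3:
            raise ValueError("complex sizes must be >= 3 (edge count >= 2)")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not (0.0 < self.within_complex_corr <= 1.0):
            raise ValueError("within_complex_corr must be in (0, 1]")
        if self.heldout_tr_per_complex >= lo - 1:
            raise ValueError("cannot withhold that many members per complex")
        needed = self.n_tfs + self.n_planted * hi
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {self.n_planted} "
                f"complexes of up to {hi} members plus {self.n_tfs} TFs"
            )


@dataclass
class PlantedComplex:
    tf: str
    members: frozenset[str]
    active_conditions: frozenset[str]
    withheld: frozenset[str]


@dataclass
class GroundTruth:
    complexes: list[PlantedComplex]
    activity: TFActivityTable
    withheld_tr_edges: list[tuple[str, str]]


@dataclass
class SyntheticData:
    tr: RegulatoryNetwork
    panel: ExpressionPanel
    ppi: PPINetwork
    truth: GroundTruth
    params: GeneratorParams = field(repr=False, default=None)


def _latent_profile(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth unit-variance time course: standardized Gaussian random walk."""
    z = np.cumsum(rng.normal(size=n))
    sd = z.std()
    if sd == 0:
        sd = 1.0
    return (z - z.mean()) / sd


def generate(params: GeneratorParams | None = None) -> SyntheticData:
    """Generate one reproducible TR/GE/PPI triple with ground truth."""
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(params.rng_seed)
    conditions = list(params.conditions)
    cond_labels = [c for c, _ in conditions]

    genes = [f"g{i:04d}" for i in range(1, params.n_genes + 1)]
    tf_ids = genes[: params.n_tfs]
    pool = genes[params.n_tfs :]

    # -- planted complexes ------------------------------------------------
    lo, hi = params.complex_size_range
    complexes: list[PlantedComplex] = []
    cursor = 0
    for k in range(params.n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = pool[cursor : cursor + size]
        cursor += size
        tf = tf_ids[k]
        active = rng.choice(
            cond_labels,
            size=min(params.active_conditions_per_complex, len(cond_labels)),
            replace=False,
        )
        withheld = members[size - params.heldout_tr_per_complex :] if (
            params.heldout_tr_per_complex
        ) else []
        complexes.append(
            PlantedComplex(
                tf=tf,
                members=frozenset(members),
                active_conditions=frozenset(str(c) for c in active),
                withheld=frozenset(withheld),
            )
        )
    background = pool[cursor:]

    # -- activity table ---------------------------------------------------
    flags: dict[tuple[str, str], bool] = {}
    planted_tf_active = {c.tf: c.active_conditions for c in complexes}
    for tf in tf_ids:
        if tf in planted_tf_active:
            for cond in cond_labels:
                flags[(tf, cond)] = cond in planted_tf_active[tf]
        else:
            # unplanted TFs: active in a random single condition
            active = str(rng.choice(cond_labels))
            for cond in cond_labels:
                flags[(tf, cond)] = cond == active
    activity = TFActivityTable(
        tfs=frozenset(tf_ids), conditions=tuple(cond_labels), flags=flags
    )

    # -- regulation table -------------------------------------------------
    tr_edges: set[tuple[str, str]] = set()
    withheld_edges: list[tuple[str, str]] = []
    for c in complexes:
        for m in sorted(c.members):
            if m in c.withheld:
                withheld_edges.append((c.tf, m))
            else:
                tr_edges.add((c.tf, m))
        # a few background targets pad the regulon realistically
        extras = rng.choice(background, size=int(rng.integers(3, 9)), replace=False)
        tr_edges.update((c.tf, str(g)) for g in extras)
    for tf in tf_ids[params.n_planted :]:
        targets = rng.choice(background, size=int(rng.integers(3, 16)), replace=False)
        tr_edges.update((tf, str(g)) for g in targets)
    tr = RegulatoryNetwork.from_edges(tr_edges)

    # -- PPI network ------------------------------------------------------
    edges: set[tuple[str, str]] = set()

    def add_edge(u: str, v: str):
        if u != v:
            edges.add((u, v) if u < v else (v, u))

    for c in complexes:
        core = sorted(c.members - c.withheld)
        held = sorted(c.withheld)
        # spanning tree over the non-withheld members keeps the seed-visible
        # part connected even when withheld members are absent
        order = list(rng.permutation(core))
        for i in range(1, len(order)):
            add_edge(order[i], str(rng.choice(order[:i])))
        # withheld members attach to >= 2 core members so annealing can
        # absorb them
        for h in held:
            partners = rng.choice(core, size=min(2, len(core)), replace=False)
            for p in partners:
                add_edge(h, str(p))
        members = sorted(c.members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < params.intra_complex_extra_edge_prob:
                    add_edge(members[i], members[j])
    # background edges over all genes
    n = len(genes)
    planted_nodes = {m for c in complexes for m in c.members}
    for i in range(n):
        for j in range(i + 1, n):
            u, v = genes[i], genes[j]
            if u in planted_nodes and v in planted_nodes:
                continue
            if rng.random() < params.background_edge_prob:
                add_edge(u, v)
    ppi = PPINetwork(sorted(edges))

    # -- expression panel -------------------------------------------------
    member_of: dict[str, PlantedComplex] = {}
    for c in complexes:
        for m in c.members:
            member_of[m] = c
    r = params.within_complex_corr
    noise_scale = math.sqrt((1.0 - r) / r) if r < 1.0 else 0.0
    frames: dict[str, pd.DataFrame] = {}
    for cond, n_t in conditions:
        latents = {
            c.tf: _latent_profile(rng, n_t) if cond in c.active_conditions else None
            for c in complexes
        }
        rows = np.empty((len(genes), n_t))
        for gi, gene in enumerate(genes):
            if gene in member_of and latents[member_of[gene].tf] is not None:
                z = latents[member_of[gene].tf]
                rows[gi] = z + rng.normal(scale=noise_scale, size=n_t)
            else:
                rows[gi] = rng.normal(scale=params.noise_sd, size=n_t)
            if gene in tf_ids and flags[(gene, cond)]:
                rows[gi] = rows[gi] + params.tf_active_shift
        if params.missing_rate > 0:
            mask = rng.random(rows.shape) < params.missing_rate
            rows[mask] = np.nan
        frames[cond] = pd.DataFrame(
            rows,
            index=pd.Index(genes, name="gene"),
            columns=[f"t{i}" for i in range(n_t)],
        )
    panel = ExpressionPanel(frames)

    truth = GroundTruth(
        complexes=complexes, activity=activity, withheld_tr_edges=withheld_edges
    )
    return SyntheticData(tr=tr, panel=panel, ppi=ppi, truth=truth, params=params)
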