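"""Inference of new TF -> gene regulatory interactions.

When the annealing extension absorbs a protein that the regulation data
does not list as a target of the seed's TF, but whose coding gene
co-expresses with the seed and whose protein interacts with it, the TF is
predicted to regulate that gene as well.  Added proteins that are already
known targets yield no prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .anneal import ExtendedComplex
from .data import PPINetwork, RegulatoryNetwork

__all__ = ["PredictedTR", "infer_new_tr"]


@dataclass
class PredictedTR:
    """A predicted TF -> target-gene regulation edge."""

    tf: str
    target_gene: str
    conditions: frozenset[str]
    evidence: dict = field(default_factory=dict)


def infer_new_tr(
    ext: ExtendedComplex,
    tr: RegulatoryNetwork,
    ppi: PPINetwork,
    per_condition: Mapping[str, ExtendedComplex] | None = None,
) -> list[PredictedTR]:
    """Predict new regulation edges from an extension's added proteins.

    ``per_condition`` (condition -> pre-intersection extension) attributes
    each prediction to the conditions whose extension contained the
    protein; without it, predictions carry the extension's own condition
    (or no condition labels for an intersected result).

    Predictions never duplicate an existing regulation edge.
    """
    tf = ext.seed.tf
    if tf is None:
        raise ValueError("seed carries no TF label; cannot infer regulation")
    known = tr.targets_of(tf)
    seed_nodes = sorted(ext.seed.nodes)
    predictions: list[PredictedTR] = []
    for protein in sorted(ext.added_nodes):
        gene = ppi.gene_of(protein)
        if gene in known:
            continue
        if per_condition is not None:
            conds = frozenset(
                c for c, e in per_condition.items() if protein in e.added_nodes
            )
        elif ext.condition is not None:
            conds = frozenset([ext.condition])
        else:
            conds = frozenset()
        predictions.append(
            PredictedTR(
                tf=tf,
                target_gene=gene,
                conditions=conds,
                evidence={
                    "seed_nodes": seed_nodes,
                    "final_score": dict(ext.result.std_score),
                },
            )
        )
    return predictions
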