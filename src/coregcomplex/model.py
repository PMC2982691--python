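"""Model/Results interface tying the discovery stages together.

:class:`ComplexDiscovery` is built from the three data sources (plus an
optional precomputed TF-activity table) and its :meth:`~ComplexDiscovery.fit`
runs the full procedure -- per-active-TF subnetworks, WCC decomposition,
candidate enumeration, null-standardized scoring, seed selection, and
optionally annealing extension with regulation inference -- returning a
:class:`DiscoveryResults` carrying the seeds, extensions, predictions and a
summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .activity import determine_active_tfs, load_activity_table
from .anneal import AnnealParams, ExtendedComplex, anneal, intersect_extensions
from .data import ExpressionPanel, PPINetwork, RegulatoryNetwork, TFActivityTable
from .inference import PredictedTR, infer_new_tr
from .io import (
    filter_unmapped_proteins,
    load_expression_panel,
    load_ppi_network,
    load_regulatory_network,
)
from .scoring import CandidateComplex, ScoringContext
from .seeds import SearchParams, enumerate_candidates, select_seeds
from .subnetwork import build_tf_subnetwork, decompose_wcc

logger = logging.getLogger(__name__)

__all__ = ["ComplexDiscovery", "DiscoveryResults"]


class ComplexDiscovery:
    """Conditional co-regulated protein-complex discovery model.

    Parameters
    ----------
    panel, regulation, ppi
        The three data sources.  The PPI network is filtered on
        construction: proteins whose coding gene has no expression profile
        in any condition are removed with their edges.
    activity
        Optional precomputed per-(TF, condition) activity table; when
        omitted, activity is called from expression levels with
        :func:`~coregcomplex.activity.determine_active_tfs` at
        ``level_quantile``.
    """

    def __init__(
        self,
        panel: ExpressionPanel,
        regulation: RegulatoryNetwork,
        ppi: PPINetwork,
        activity: TFActivityTable | None = None,
        level_quantile: float = 0.75,
    ):
        self.panel = panel
        self.regulation = regulation
        self.ppi = filter_unmapped_proteins(ppi, panel)
        if activity is None:
            activity = determine_active_tfs(panel, regulation.tfs, level_quantile)
        self.activity = activity

    @classmethod
    def from_files(
        cls,
        expression: Mapping[str, str | Path],
        regulation: str | Path,
        ppi: str | Path,
        activity_file: str | Path | None = None,
        gene_map: Mapping[str, str] | None = None,
        level_quantile: float = 0.75,
    ) -> "ComplexDiscovery":
        panel = load_expression_panel(expression)
        tr = load_regulatory_network(regulation)
        net = load_ppi_network(ppi, gene_map=gene_map)
        act = (
            load_activity_table(activity_file, tr.tfs, panel.conditions)
            if activity_file is not None
            else None
        )
        return cls(panel, tr, net, activity=act, level_quantile=level_quantile)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        search: SearchParams | None = None,
        anneal_params: AnnealParams | None = None,
        extend: str = "perfect",
    ) -> "DiscoveryResults":
        """Run seed discovery, then (optionally) extension and inference.

        ``extend`` selects which seeds are annealed: ``"perfect"`` (default)
        extends only seeds whose score degree agrees with their TF's
        activity in every condition, ``"all"`` extends every seed, and
        ``"none"`` stops after seed discovery.
        """
        if search is None:
            search = SearchParams()
        if extend not in ("perfect", "all", "none"):
            raise ValueError(f"unknown extend mode {extend!r}")
        context = ScoringContext(
            self.ppi,
            self.panel,
            n_samples=search.n_random,
            base_seed=search.rng_seed,
        )
        conditions = self.panel.conditions
        active_anywhere = sorted(
            tf
            for tf in self.regulation.tfs
            if any(self.activity.is_active(tf, c) for c in conditions)
        )
        if not active_anywhere:
            logger.warning("no TF is active in any condition; empty result")
        candidates: list[CandidateComplex] = []
        n_wccs = 0
        for tf in active_anywhere:
            sub = build_tf_subnetwork(tf, self.regulation, self.ppi)
            for wcc in decompose_wcc(sub):
                n_wccs += 1
                rank_fn = lambda edges, _c=conditions: max(  # noqa: E731
                    float(context.raw_score_edges(edges, c)) for c in _c
                )
                candidates.extend(
                    enumerate_candidates(
                        wcc,
                        lambda_min=search.lambda_min,
                        beta_max=search.beta_max,
                        work_budget=search.work_budget,
                        beam_width=search.beam_width,
                        rank_fn=rank_fn,
                    )
                )
        logger.info(
            "%d active TF(s), %d WCC(s), %d candidate(s)",
            len(active_anywhere),
            n_wccs,
            len(candidates),
        )
        seeds = select_seeds(candidates, self.activity, search, context)
        logger.info("%d seed(s) selected", len(seeds))

        extensions: dict[int, dict[str, ExtendedComplex]] = {}
        intersected: dict[int, ExtendedComplex] = {}
        predictions: list[PredictedTR] = []
        if extend != "none" and anneal_params is not None:
            for idx, seed in enumerate(seeds):
                if extend == "perfect" and seed.consistency != len(conditions):
                    continue
                active_conds = [
                    c for c in conditions if self.activity.is_active(seed.tf, c)
                ]
                if not active_conds:
                    continue
                per_cond: dict[str, ExtendedComplex] = {}
                for cond in active_conds:
                    params_c = AnnealParams(
                        t_start=anneal_params.t_start,
                        t_end=anneal_params.t_end,
                        n_iter=anneal_params.n_iter,
                        rng_seed=(anneal_params.rng_seed + 7919 * idx) % (2**31),
                    )
                    per_cond[cond] = anneal(seed, self.ppi, context, cond, params_c)
                combined = intersect_extensions(list(per_cond.values()), self.ppi)
                extensions[idx] = per_cond
                intersected[idx] = combined
                predictions.extend(
                    infer_new_tr(combined, self.regulation, self.ppi, per_cond)
                )
        return DiscoveryResults(
            model=self,
            search=search,
            anneal_params=anneal_params,
            seeds=seeds,
            extensions=extensions,
            intersected=intersected,
            predictions=predictions,
            context=context,
        )


@dataclass
class DiscoveryResults:
    """Seeds, extensions and predicted regulations from one fit."""

    model: ComplexDiscovery
    search: SearchParams
    anneal_params: AnnealParams | None
    seeds: list[CandidateComplex]
    extensions: dict[int, dict[str, ExtendedComplex]]
    intersected: dict[int, ExtendedComplex]
    predictions: list[PredictedTR]
    context: ScoringContext = field(repr=False, default=None)

    # -- tabular views ----------------------------------------------------

    def seeds_frame(self):
        """Seed table: TF, members, per-condition T / Score / activity."""
        import pandas as pd

        conditions = self.model.panel.conditions
        rows = []
        for seed in self.seeds:
            row: dict = {
                "tf": seed.tf,
                "nodes": ";".join(seed.sorted_nodes()),
                "n_edges": seed.n_edges,
            }
            for c in conditions:
                row[f"T_{c}"] = seed.raw_T.get(c)
                row[f"score_{c}"] = seed.std_score.get(c)
                row[f"active_{c}"] = (
                    "T" if self.model.activity.is_active(seed.tf, c) else "F"
                )
            row["consistency"] = seed.consistency
            rows.append(row)
        return pd.DataFrame(rows)

    def predictions_frame(self):
        """Predicted regulations: condition(s), TF, target gene."""
        import pandas as pd

        rows = [
            {
                "conditions": ",".join(sorted(p.conditions)),
                "tf": p.tf,
                "predicted_target": p.target_gene,
            }
            for p in self.predictions
        ]
        return pd.DataFrame(rows, columns=["conditions", "tf", "predicted_target"])

    def write_reports(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        seeds_path = out_dir / "seeds.tsv"
        self.seeds_frame().to_csv(seeds_path, sep="\t", index=False)
        written.append(seeds_path)
        pred_path = out_dir / "predicted_tr.tsv"
        self.predictions_frame().to_csv(pred_path, sep="\t", index=False)
        written.append(pred_path)
        for idx, per_cond in self.extensions.items():
            for cond, ext in per_cond.items():
                trace_path = out_dir / f"trace_seed{idx}_{cond}.tsv"
                ext.write_trace(trace_path)
                written.append(trace_path)
        return written

    def summary(self) -> str:
        """Human-readable run summary."""
        conditions = self.model.panel.conditions
        lines = [
            "Conditional co-regulated complex discovery",
            "=" * 58,
            f"conditions:       {', '.join(conditions)}",
            f"proteins (PPI):   {len(self.model.ppi.proteins)}"
            f" / edges: {self.model.ppi.n_edges()}",
            f"regulations (TR): {len(self.model.regulation)}",
            f"score threshold:  alpha={self.search.alpha}"
            f"  theta={self.search.theta}"
            f"  edges in [{self.search.lambda_min}, {self.search.beta_max}]",
            f"null samples:     {self.search.n_random} per (condition, K)",
            f"seeds selected:   {len(self.seeds)}",
        ]
        if self.seeds:
            lines.append("-" * 58)
            header = f"{'tf':<10}{'edges':>6}" + "".join(
                f"{('score_' + c):>12}" for c in conditions
            )
            lines.append(header)
            for seed in self.seeds:
                lines.append(
                    f"{seed.tf:<10}{seed.n_edges:>6}"
                    + "".join(
                        f"{seed.std_score.get(c, float('nan')):>12.2f}"
                        for c in conditions
                    )
                )
        if self.intersected:
            lines.append("-" * 58)
            lines.append(f"extended seeds:   {len(self.intersected)}")
            lines.append(f"predicted TRs:    {len(self.predictions)}")
            for p in self.predictions:
                conds = ",".join(sorted(p.conditions)) or "-"
                lines.append(f"  {conds:<10}{p.tf:<10}-> {p.target_gene}")
        return "\n".join(lines)

    def plot_trace(self, seed_index: int, condition: str, ax=None):
        """Score/edge trajectory of one annealing run (needs matplotlib)."""
        import matplotlib.pyplot as plt

        ext = self.extensions[seed_index][condition]
        iters = [t[0] for t in ext.score_trace]
        scores = [t[2] for t in ext.score_trace]
        n_edges = [t[3] for t in ext.score_trace]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(iters, scores, label="Score(L)")
        ax2 = ax.twinx()
        ax2.plot(iters, n_edges, color="grey", alpha=0.6, label="edges")
        ax.set_xlabel("iteration")
        ax.set_ylabel("standardized score")
        ax2.set_ylabel("edge count")
        return ax
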