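"""Candidate enumeration, overlap deduplication and seed selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coregcomplex import (
    CandidateComplex,
    PPINetwork,
    RegulatoryNetwork,
    ScoringContext,
    SearchParams,
    consistency_count,
    deduplicate_overlap,
    determine_active_tfs,
    enumerate_candidates,
    select_seeds,
)
from coregcomplex.data import TFActivityTable
from coregcomplex.subnetwork import WCC

from conftest import make_panel


def _wcc(edges, tf="tf"):
    return WCC(tf=tf, graph=nx.Graph(edges))


def _edge_sets(cands):
    return {c.edges for c in cands}


def brute_force_connected_subgraphs(graph, lo, hi):
    """Oracle: filter all edge subsets for connectivity."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    out = set()
    for k in range(lo, hi + 1):
        for comb in itertools.combinations(edges, k):
            if nx.is_connected(nx.Graph(list(comb))):
                out.add(frozenset(comb))
    return out


class TestEnumeration:
    def test_path_graph_yields_three_candidates(self):
        wcc = _wcc([("a", "b"), ("b", "c"), ("c", "d")])
        got = _edge_sets(enumerate_candidates(wcc, 2, 21))
        assert got == {
            frozenset({("a", "b"), ("b", "c")}),
            frozenset({("b", "c"), ("c", "d")}),
            frozenset({("a", "b"), ("b", "c"), ("c", "d")}),
        }

    def test_triangle_yields_four_candidates(self):
        wcc = _wcc([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(_edge_sets(enumerate_candidates(wcc, 2, 21))) == 4

    def test_single_edge_below_lambda_is_empty(self):
        wcc = _wcc([("a", "b")])
        assert list(enumerate_candidates(wcc, 2, 21)) == []

    def test_each_candidate_yielded_once(self):
        g = nx.gnp_random_graph(6, 0.5, seed=17)
        g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(6)})
        cands = [c.edges for c in enumerate_candidates(_wcc(g.edges), 1, 8)]
        assert len(cands) == len(set(cands))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(6, rng.uniform(0.3, 0.7), seed=seed + 100)
        g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(6)})
        if g.number_of_edges() > 8 or g.number_of_edges() == 0:
            g = nx.path_graph([f"p{i}" for i in range(5)])
        got = _edge_sets(enumerate_candidates(_wcc(g.edges), 1, 8))
        assert got == brute_force_connected_subgraphs(g, 1, 8)

    def test_beta_caps_edge_count(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        for cand in enumerate_candidates(_wcc(g.edges), 2, 3):
            assert 2 <= cand.n_edges <= 3

    def test_beam_fallback_still_yields_valid_candidates(self):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        g = nx.relabel_nodes(g, {i: f"p{i:02d}" for i in range(12)})
        cands = list(
            enumerate_candidates(_wcc(g.edges), 2, 6, work_budget=50, beam_width=40)
        )
        assert cands
        exact = brute_force_connected_subgraphs(g, 2, 6)
        for c in cands:
            assert c.edges in exact  # beam output is a subset of the truth


class TestDeduplication:
    def _cand(self, nodes, score):
        nodes = frozenset(nodes)
        edges = frozenset(
            (a, b)
            for a, b in zip(sorted(nodes), sorted(nodes)[1:])
        )
        c = CandidateComplex(nodes=nodes, edges=edges)
        c.std_score["c1"] = score
        return c

    def test_identical_node_sets_keep_higher_score(self):
        lo = self._cand("abc", 1.0)
        hi = self._cand("abc", 2.0)
        kept = deduplicate_overlap([lo, hi], 0.8)
        assert kept == [hi]

    def test_disjoint_sets_both_kept(self):
        kept = deduplicate_overlap([self._cand("abc", 1.0), self._cand("xyz", 2.0)], 0.8)
        assert len(kept) == 2

    def test_four_of_five_shared_removes_lower(self):
        a = self._cand("abcde", 3.0)
        b = self._cand("abcdf", 2.0)  # shares 4/5 = 0.8 -> duplicate
        kept = deduplicate_overlap([a, b], 0.8)
        assert kept == [a]

    def test_idempotent_and_no_violations(self):
        rng = np.random.default_rng(6)
        letters = "abcdefghij"
        cands = [
            self._cand(
                rng.choice(list(letters), size=rng.integers(3, 6), replace=False),
                float(rng.normal()),
            )
            for _ in range(20)
        ]
        kept = deduplicate_overlap(cands, 0.8)
        again = deduplicate_overlap(kept, 0.8)
        assert _edge_sets(again) == _edge_sets(kept)
        for x, y in itertools.combinations(kept, 2):
            ov = len(x.nodes & y.nodes) / min(len(x.nodes), len(y.nodes))
            assert ov < 0.8

    def test_subset_counts_as_full_overlap_under_min_denominator(self):
        big = self._cand("abcde", 1.0)
        small = self._cand("abc", 5.0)
        kept = deduplicate_overlap([big, small], 0.8)
        assert kept == [small]  # higher score wins; big overlaps 3/3


class TestConsistency:
    def test_active_one_condition_all_consistent(self):
        scores = {"c1": 3.18, "c2": -0.49, "c3": 0.25}
        activity = {"c1": True, "c2": False, "c3": False}
        assert consistency_count(scores, activity, alpha=1.90) == 3

    def test_all_active_all_high(self):
        scores = {"c1": 2.0, "c2": 2.5, "c3": 3.0}
        activity = {c: True for c in scores}
        assert consistency_count(scores, activity, 1.9) == 3

    def test_high_scores_under_inactive_tf_disagree(self):
        scores = {"c1": 2.0, "c2": 2.5, "c3": 3.0}
        activity = {"c1": True, "c2": False, "c3": False}
        assert consistency_count(scores, activity, 1.9) == 1

    def test_key_mismatch_raises(self):
        with pytest.raises(KeyError):
            consistency_count({"c1": 1.0}, {"c2": True}, 1.9)


class TestSelection:
    def _setup(self):
        rng = np.random.default_rng(31)
        latent = np.cumsum(rng.normal(size=20))
        latent = (latent - latent.mean()) / latent.std()
        profiles = {g: latent + rng.normal(scale=0.15, size=20) for g in "abcd"}
        bg = [f"x{i:02d}" for i in range(16)]
        profiles.update({g: rng.normal(size=20) for g in bg})
        # make the shared-profile TF itself highly expressed
        profiles["tf1"] = rng.normal(size=20) + 5.0
        profiles["tf2"] = rng.normal(size=20)
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")]
        for i in range(len(bg)):
            for j in range(i + 1, len(bg)):
                if rng.random() < 0.2:
                    edges.append((bg[i], bg[j]))
        panel = make_panel(profiles)
        ppi = PPINetwork(edges)
        tr = RegulatoryNetwork.from_edges(
            [("tf1", g) for g in "abcd"] + [("tf2", g) for g in bg[:4]]
        )
        activity = determine_active_tfs(panel, tr.tfs, 0.75)
        context = ScoringContext(ppi, panel, n_samples=500, base_seed=0)
        return panel, ppi, tr, activity, context

    def _candidates(self, ppi):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")]
        full = CandidateComplex(frozenset("abcd"), frozenset(edges), tf="tf1")
        pair = CandidateComplex(
            frozenset("abc"), frozenset({("a", "b"), ("b", "c")}), tf="tf1"
        )
        return [full, pair]

    def test_low_scores_rejected_high_kept(self):
        panel, ppi, tr, activity, context = self._setup()
        params = SearchParams(n_random=500, theta=1)
        seeds = select_seeds(self._candidates(ppi), activity, params, context)
        assert seeds  # coherent complex passes
        sky_high = SearchParams(alpha=1e6, n_random=500, theta=1)
        context2 = ScoringContext(ppi, panel, n_samples=500, base_seed=0)
        assert (
            select_seeds(self._candidates(ppi), activity, sky_high, context2) == []
        )

    def test_overlapping_candidates_collapse_to_one(self):
        panel, ppi, tr, activity, context = self._setup()
        params = SearchParams(n_random=500, theta=1)
        seeds = select_seeds(self._candidates(ppi), activity, params, context)
        assert len(seeds) == 1  # abc is a subset of abcd -> full overlap

    @pytest.mark.parametrize("which", ["alpha", "theta"])
    def test_raising_threshold_never_enlarges_seed_set(self, which):
        panel, ppi, tr, activity, context = self._setup()
        base = SearchParams(n_random=500, theta=1)
        seeds_lo = select_seeds(self._candidates(ppi), activity, base, context)
        if which == "alpha":
            strict = SearchParams(alpha=base.alpha + 2.0, n_random=500, theta=1)
        else:
            strict = SearchParams(n_random=500, theta=3)
        seeds_hi = select_seeds(self._candidates(ppi), activity, strict, context)
        assert _edge_sets(seeds_hi) <= _edge_sets(seeds_lo)

    def test_candidate_without_tf_rejected(self):
        panel, ppi, tr, activity, context = self._setup()
        cand = CandidateComplex(frozenset("ab"), frozenset({("a", "b")}))
        with pytest.raises(ValueError, match="TF label"):
            select_seeds([cand], activity, SearchParams(n_random=500), context)


class TestSearchParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"lambda_min": 0},
            {"lambda_min": 5, "beta_max": 3},
            {"overlap_frac": 0.0},
            {"overlap_frac": 1.2},
            {"theta": 0},
            {"overlap_denominator": "bogus"},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SearchParams(**kw)

    def test_defaults_match_documented_study_settings(self):
        p = SearchParams()
        assert (p.lambda_min, p.beta_max) == (2, 21)
        assert p.alpha == pytest.approx(1.90)
        assert p.theta == 2
        assert p.overlap_frac == pytest.approx(0.8)
        assert p.n_random == 10_000
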