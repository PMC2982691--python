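"""Edge coherence, additive raw score, and the randomization null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coregcomplex import (
    CandidateComplex,
    DegenerateReferenceError,
    PPINetwork,
    ScoringContext,
    UndefinedCoherenceError,
    edge_coherence,
    raw_score,
    sample_random_reference,
    standardized_score,
)

from conftest import make_panel


class TestEdgeCoherence:
    def test_identical_profiles_give_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert edge_coherence(x, x) == pytest.approx(1.0)

    def test_negated_profile_gives_minus_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert edge_coherence(x, -x) == pytest.approx(-1.0)

    def test_pairwise_complete_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([2.0, 4.0, 6.0, 7.0, 10.0])
        xs, ys = np.array([1, 2, 3, 5.0]), np.array([2, 4, 6, 10.0])
        expected = (
            ((xs - xs.mean()) * (ys - ys.mean())).sum()
            / np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        )
        assert edge_coherence(x, y) == pytest.approx(expected, abs=1e-15)

    def test_fewer_than_three_pairs_is_undefined(self):
        x = np.array([1.0, np.nan, 3.0, np.nan])
        y = np.array([2.0, 4.0, np.nan, 8.0])
        assert edge_coherence(x, y) is None

    def test_constant_retained_profile_is_undefined(self):
        assert edge_coherence([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetric_and_bounded(self, values, seed):
        rng = np.random.default_rng(seed)
        x = np.array(values)
        y = x + rng.normal(size=len(x))
        r_xy = edge_coherence(x, y)
        r_yx = edge_coherence(y, x)
        if r_xy is None:
            assert r_yx is None
        else:
            assert r_xy == pytest.approx(r_yx)
            assert -1.0 <= r_xy <= 1.0


class TestRawScore:
    def test_identical_member_profiles_score_edge_count(self):
        x = [1.0, 4.0, 2.0, 6.0]
        panel = make_panel({g: x for g in "abc"})
        cand = CandidateComplex(
            nodes=frozenset("abc"), edges=frozenset({("a", "b"), ("b", "c")})
        )
        t = raw_score(cand, panel, "c1")
        assert float(t) == pytest.approx(2.0)
        assert t.covered

    def test_absent_member_gene_scores_zero_with_flag(self):
        panel = make_panel({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        cand = CandidateComplex(
            nodes=frozenset("abc"), edges=frozenset({("a", "b"), ("b", "c")})
        )
        t = raw_score(cand, panel, "c1")
        assert float(t) == 0.0
        assert not t.covered

    def test_undefined_coherence_on_covered_edge_names_it(self):
        panel = make_panel({"a": [1.0, 1.0, 1.0], "b": [2.0, 1.0, 3.0]})
        cand = CandidateComplex(nodes=frozenset("ab"), edges=frozenset({("a", "b")}))
        with pytest.raises(UndefinedCoherenceError, match=r"\(a, b\)"):
            raw_score(cand, panel, "c1")

    def test_invariant_under_edge_ordering_and_relabeling(self):
        rng = np.random.default_rng(2)
        panel = make_panel({g: rng.normal(size=8) for g in "abcd"})
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")]
        t1 = raw_score(
            CandidateComplex(frozenset("abcd"), frozenset(edges)), panel, "c1"
        )
        flipped = [(v, u) for u, v in reversed(edges)]
        t2 = raw_score(
            CandidateComplex(frozenset("abcd"), frozenset(flipped)), panel, "c1"
        )
        assert float(t1) == pytest.approx(float(t2), abs=1e-15)

    def test_disconnected_candidate_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            CandidateComplex(
                nodes=frozenset("abcd"), edges=frozenset({("a", "b"), ("c", "d")})
            )


def _exhaustive_adjacent_pair_scores(ppi, panel, condition):
    """All connected 2-edge subgraph scores by direct enumeration."""
    edges = sorted(ppi.edges())
    vals = {}
    for u, v in edges:
        vals[(u, v)] = edge_coherence(
            panel.profile(u, condition), panel.profile(v, condition)
        )
    out = []
    for e1, e2 in itertools.combinations(edges, 2):
        if set(e1) & set(e2):
            out.append(vals[e1] + vals[e2])
    return np.array(out)


class TestRandomReference:
    def test_single_subgraph_ppi_is_degenerate(self):
        panel = make_panel({"a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 3.0],
                            "c": [3.0, 1.0, 2.0]})
        ppi = PPINetwork([("a", "b"), ("b", "c")])
        ref = sample_random_reference(ppi, K=2, panel=panel, condition="c1",
                                      n=50, seed=0)
        assert ref.degenerate
        with pytest.raises(DegenerateReferenceError):
            standardized_score(1.0, ref)

    def test_sampled_mean_matches_exhaustive_enumeration(self, cycle_fixture):
        ppi, panel = cycle_fixture
        exact = _exhaustive_adjacent_pair_scores(ppi, panel, "c1")
        ref = sample_random_reference(
            ppi, K=2, panel=panel, condition="c1", n=10_000, seed=42,
            keep_samples=True,
        )
        se = exact.std(ddof=0) / np.sqrt(ref.n_samples)
        assert abs(ref.mean_T - exact.mean()) < 3 * se

    def test_empirical_tail_matches_enumeration(self, cycle_fixture):
        # fraction of sampled T above a cutoff vs the exact tail fraction
        ppi, panel = cycle_fixture
        exact = _exhaustive_adjacent_pair_scores(ppi, panel, "c1")
        cutoff = float(np.quantile(exact, 0.9))
        p_exact = float((exact > cutoff).mean())
        ref = sample_random_reference(
            ppi, K=2, panel=panel, condition="c1", n=10_000, seed=7,
            keep_samples=True,
        )
        p_hat = float((ref.samples > cutoff).mean())
        ci = 3 * np.sqrt(p_exact * (1 - p_exact) / ref.n_samples)
        assert abs(p_hat - p_exact) < ci

    def test_deterministic_given_seed(self, cycle_fixture):
        ppi, panel = cycle_fixture
        a = sample_random_reference(ppi, 3, panel, "c1", n=200, seed=5)
        b = sample_random_reference(ppi, 3, panel, "c1", n=200, seed=5)
        assert (a.mean_T, a.std_T) == (b.mean_T, b.std_T)

    def test_n_defaults_to_ten_thousand(self, cycle_fixture):
        ppi, panel = cycle_fixture
        ref = sample_random_reference(ppi, 2, panel, "c1", seed=1)
        assert ref.n_samples == 10_000

    def test_samples_are_connected_with_k_edges(self, cycle_fixture):
        import networkx as nx

        from coregcomplex.scoring import _sample_connected_edge_sets

        ppi, _ = cycle_fixture
        rng = np.random.default_rng(3)
        edges = sorted(ppi.edges())
        for idxs in _sample_connected_edge_sets(ppi, 4, 100, rng):
            assert len(idxs) == 4
            g = nx.Graph([edges[i] for i in idxs])
            assert nx.is_connected(g)

    def test_edge_set_null_available(self, cycle_fixture):
        ppi, panel = cycle_fixture
        ref = sample_random_reference(
            ppi, 2, panel, "c1", n=500, seed=1, null="edge-set"
        )
        assert ref.n_samples == 500


class TestStandardization:
    def test_centering_and_scaling(self):
        from coregcomplex.scoring import RandomScoreReference

        ref = RandomScoreReference(3, mean_T=0.4, std_T=0.2, n_samples=100,
                                   condition="c1", rng_seed=0)
        assert standardized_score(0.4, ref) == pytest.approx(0.0)
        assert standardized_score(0.6, ref) == pytest.approx(1.0)

    def test_population_self_zscore_is_standard(self, cycle_fixture):
        ppi, panel = cycle_fixture
        ref = sample_random_reference(
            ppi, 2, panel, "c1", n=10_000, seed=11, keep_samples=True
        )
        z = (ref.samples - ref.mean_T) / ref.std_T
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_equal_raw_and_k_give_equal_score(self, cycle_fixture):
        ppi, panel = cycle_fixture
        ref = sample_random_reference(ppi, 2, panel, "c1", n=500, seed=2)
        assert standardized_score(0.33, ref) == standardized_score(0.33, ref)


class TestScoringContext:
    def test_no_coverage_reported_as_zero_score(self):
        panel = make_panel({"a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 3.0],
                            "x": [0.5, 1.5, 0.7], "y": [1.1, 0.3, 2.2],
                            "z": [0.2, 2.0, 1.0]})
        ppi = PPINetwork([("a", "b"), ("b", "q"), ("x", "y"), ("y", "z"),
                          ("x", "z"), ("a", "x")])
        context = ScoringContext(ppi, panel, n_samples=100, base_seed=0)
        cand = CandidateComplex(
            nodes=frozenset({"a", "b", "q"}),
            edges=frozenset({("a", "b"), ("b", "q")}),
        )
        context.score_candidate(cand)
        assert cand.raw_T["c1"] == 0.0
        assert cand.no_coverage["c1"]
        assert cand.std_score["c1"] == 0.0

    def test_reference_cache_round_trips(self, cycle_fixture, tmp_path):
        ppi, panel = cycle_fixture
        ctx = ScoringContext(ppi, panel, n_samples=300, base_seed=1)
        ref = ctx.reference(2, "c1")
        path = tmp_path / "refs.tsv"
        ctx.save_references(path)
        ctx2 = ScoringContext(ppi, panel, n_samples=300, base_seed=1)
        assert ctx2.load_references(path) == 1
        ref2 = ctx2.reference(2, "c1")
        assert (ref2.mean_T, ref2.std_T) == (ref.mean_T, ref.std_T)
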