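"""Shared fixtures: small panels, PPI graphs and annealing testbeds.

All fixtures are generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coregcomplex import ExpressionPanel, PPINetwork, RegulatoryNetwork


def make_panel(arrays: dict, condition: str = "c1") -> ExpressionPanel:
    """Panel for one condition from {gene: list-of-values}."""
    df = pd.DataFrame.from_dict(arrays, orient="index", dtype=float)
    df.index.name = "gene"
    df.columns = [f"t{i}" for i in range(df.shape[1])]
    return ExpressionPanel({condition: df})


@pytest.fixture
def tiny_panel() -> ExpressionPanel:
    """3 genes x 4 time points, one missing value."""
    return make_panel(
        {
            "g1": [1.0, 2.0, 3.0, 4.0],
            "g2": [2.0, 4.0, 6.0, 8.0],
            "g3": [1.0, np.nan, 2.0, 1.5],
        }
    )


@pytest.fixture
def cycle_fixture():
    """12-edge cycle PPI with random 20-point profiles (2-regular graph).

    On a regular graph the connected-growth null sampler is uniform over
    adjacent edge pairs, so exhaustive enumeration of 2-edge subgraphs is
    an exact oracle for the sampled null mean.
    """
    rng = np.random.default_rng(7)
    nodes = [f"n{i:02d}" for i in range(12)]
    edges = [(nodes[i], nodes[(i + 1) % 12]) for i in range(12)]
    ppi = PPINetwork(edges)
    panel = make_panel({n: rng.normal(size=20) for n in nodes})
    return ppi, panel


@pytest.fixture
def good_vertex_fixture():
    """Annealing testbed: seed path a-b-c plus one clearly beneficial vertex.

    Gene d shares the seed's latent profile and interacts with b and c;
    background genes carry independent profiles and random edges so the
    null reference has spread.
    """
    rng = np.random.default_rng(11)
    latent = np.cumsum(rng.normal(size=30))
    latent = (latent - latent.mean()) / latent.std()
    profiles = {g: latent + rng.normal(scale=0.2, size=30) for g in "abcd"}
    # a background large enough that the null is dominated by uncorrelated
    # pairs (null mean ~ 0, std ~ sqrt(K)), so absorbing d is an uphill move
    bg = [f"x{i:02d}" for i in range(100)]
    profiles.update({g: rng.normal(size=30) for g in bg})
    edges = [("a", "b"), ("b", "c"), ("b", "d"), ("c", "d")]
    for i in range(len(bg)):
        for j in range(i + 1, len(bg)):
            if rng.random() < 0.04:
                edges.append((bg[i], bg[j]))
    # a few background attachments to the seed so non-beneficial moves exist
    for g in ("a", "b", "c"):
        partners = rng.choice(bg, size=2, replace=False)
        edges.extend((g, str(p)) for p in partners)
    ppi = PPINetwork(edges)
    panel = make_panel(profiles)
    seed_edges = frozenset({("a", "b"), ("b", "c")})
    return ppi, panel, seed_edges


@pytest.fixture
def small_tr() -> RegulatoryNetwork:
    return RegulatoryNetwork.from_edges(
        [("tf1", "a"), ("tf1", "b"), ("tf1", "c"), ("tf2", "b"), ("tf2", "d")]
    )
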