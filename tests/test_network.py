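"""Co-expression graph construction and k-core topology, against oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hepacore as h
from hepacore.synthetic import SyntheticSpec

from conftest import make_matrix


def brute_force_kcore(graph: nx.Graph, k: int) -> set:
    """Oracle: repeatedly delete vertices of degree < k."""
    g = graph.copy()
    while True:
        drop = [n for n, d in g.degree() if d < k]
        if not drop:
            return set(g.nodes)
        g.remove_nodes_from(drop)


def brute_force_core_numbers(graph: nx.Graph) -> dict:
    cores = {n: 0 for n in graph.nodes}
    k = 0
    while True:
        k += 1
        members = brute_force_kcore(graph, k)
        if not members:
            return cores
        for n in members:
            cores[n] = k


# ------------------------------------------------------------- correlation

def test_correlation_duplicate_and_negated_gene(four_group_design):
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, 12)
    m = make_matrix(np.vstack([base, base, -base]), four_group_design)
    r = h.correlation_matrix(m)
    assert r.iloc[0, 1] == pytest.approx(1.0)
    assert r.iloc[0, 2] == pytest.approx(-1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T)
    assert np.allclose(np.diag(r), 1.0)


def test_correlation_matches_direct_formula(four_group_design):
    rng = np.random.default_rng(1)
    values = rng.normal(8, 1, (50, 12))
    m = make_matrix(values, four_group_design)
    r = h.correlation_matrix(m).to_numpy()
    centered = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    oracle = (centered @ centered.T) / np.outer(sd, sd)
    assert np.abs(r - oracle).max() < 1e-10


def test_correlation_zero_variance_flagged(four_group_design):
    values = np.vstack([np.random.default_rng(2).normal(0, 1, 12), np.full(12, 3.0)])
    m = make_matrix(values, four_group_design)
    r = h.correlation_matrix(m)
    assert r.iloc[0, 1] == 0.0 and r.iloc[1, 1] == 1.0
    assert r.attrs["zero_variance"] == ["g2"]
    assert np.isfinite(r.to_numpy()).all()


# ------------------------------------------------------------------ graph

def test_build_graph_threshold_and_rules():
    r = pd.DataFrame(
        [[1.0, 0.95, -0.95], [0.95, 1.0, 0.5], [-0.95, 0.5, 1.0]],
        index=list("abc"), columns=list("abc"),
    )
    absolute = h.build_graph(r, 0.9, "absolute")
    assert absolute.has_edge("a", "b") and absolute.has_edge("a", "c")
    assert not absolute.has_edge("b", "c")
    assert absolute["a"]["c"]["weight"] == pytest.approx(-0.95)
    positive = h.build_graph(r, 0.9, "positive")
    assert positive.has_edge("a", "b") and not positive.has_edge("a", "c")
    with pytest.raises(ValueError, match="threshold"):
        h.build_graph(r, 1.5)
    with pytest.raises(ValueError, match="rule"):
        h.build_graph(r, 0.9, "signed")


def test_null_edge_density_matches_closed_form():
    """Independent Gaussian genes at n=12: edge density of the |r| >= 0.9
    graph matches P(|r| >= 0.9) from r^2 ~ Beta(1/2, (n-2)/2), within 3
    Monte-Carlo SE over independent replicate matrices."""
    n_samples = 12
    p_edge = stats.beta(0.5, (n_samples - 2) / 2).sf(0.81)
    densities = []
    for seed in range(40):
        m, _ = h.generate_null_matrix(SyntheticSpec(n_genes=200, seed=300 + seed))
        g = h.build_graph(h.correlation_matrix(m), 0.9)
        n_pairs = 200 * 199 / 2
        densities.append(g.number_of_edges() / n_pairs)
    densities = np.asarray(densities)
    se = densities.std(ddof=1) / np.sqrt(len(densities))
    assert abs(densities.mean() - p_edge) <= 3 * se


# --------------------------------------------------------------- topology

def test_topology_triangle_star_complete():
    topo = h.node_topology(nx.complete_graph(3))
    assert (topo["degree"] == 2).all()
    assert (topo["clustering"] == 1.0).all()
    assert (topo["core"] == 2).all()

    star = h.node_topology(nx.star_graph(5))  # center 0, 5 leaves
    center = star[star["gene"] == 0].iloc[0]
    assert center["degree"] == 5 and center["clustering"] == 0.0
    assert (star["core"] == 1).all()

    k6 = h.node_topology(nx.complete_graph(6))
    assert (k6["core"] == 5).all()


def test_clustering_coefficient_forward_from_printed_value():
    """A published hub's printed C inverts to an integer neighbour-edge
    count and recomputes forward: a node with k=34 neighbours and e=235
    edges among them has C = 235/561 = 0.418894827 (7 significant figures),
    verified on an explicitly constructed graph."""
    k, printed = 34, 0.418894827
    e = round(printed * k * (k - 1) / 2)
    assert e == 235
    g = nx.star_graph(k)  # center 0 with neighbours 1..34
    added = 0
    for i in range(1, k + 1):
        for j in range(i + 1, k + 1):
            if added == e:
                break
            g.add_edge(i, j)
            added += 1
    topo = h.node_topology(g)
    c = topo.loc[topo["gene"] == 0, "clustering"].iloc[0]
    assert c == pytest.approx(printed, abs=5e-8)
    assert c == pytest.approx(e / (k * (k - 1) / 2))


def test_hub_table_internal_consistency():
    """Every printed (C, k) pair in the reference hub table satisfies the
    local clustering definition: C * k(k-1)/2 is an integer to 1e-4."""
    table = h.reference_hub_table()
    assert len(table) == 26
    e = table["clustering"] * table["degree"] * (table["degree"] - 1) / 2
    assert np.abs(e - e.round()).max() < 1e-4
    assert (table["core"] <= table["degree"]).all()


# ----------------------------------------------------------------- k-core

def test_kcore_trivial_cases():
    k5 = nx.complete_graph(5)
    assert set(h.kcore_subgraph(k5, 4).nodes) == set(k5.nodes)
    assert h.kcore_subgraph(k5, 5).number_of_nodes() == 0
    path = nx.path_graph(10)
    assert h.kcore_subgraph(path, 2).number_of_nodes() == 0
    with pytest.raises(ValueError):
        h.kcore_subgraph(k5, -1)


def test_kcore_equals_bruteforce_on_random_graphs():
    for seed in range(50):
        g = nx.gnp_random_graph(30, 0.2, seed=seed)
        oracle_cores = brute_force_core_numbers(g)
        topo = h.node_topology(g).set_index("gene")
        for node, core in oracle_cores.items():
            assert topo.loc[node, "core"] == core
        for k in range(0, max(oracle_cores.values()) + 2):
            assert set(h.kcore_subgraph(g, k).nodes) == brute_force_kcore(g, k)


def test_kcore_nesting_and_degree_bound():
    g = nx.gnp_random_graph(40, 0.15, seed=99)
    topo = h.node_topology(g).set_index("gene")
    assert (topo["core"] <= topo["degree"]).all()
    assert topo["clustering"].between(0, 1).all()
    prev = set(g.nodes)
    for k in range(1, int(topo["core"].max()) + 2):
        cur = set(h.kcore_subgraph(g, k).nodes)
        assert cur <= prev
        prev = cur


def test_edge_removal_never_raises_core():
    rng = np.random.default_rng(5)
    for seed in range(10):
        g = nx.gnp_random_graph(25, 0.25, seed=seed)
        if g.number_of_edges() == 0:
            continue
        before = nx.core_number(g)
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        g2 = g.copy()
        g2.remove_edge(u, v)
        after = nx.core_number(g2)
        assert all(after[n] <= before[n] for n in g.nodes)


# ------------------------------------------------------------- core genes

def test_select_core_genes_depth_rule():
    topo = pd.DataFrame(
        {"gene": list("ABCD"), "clustering": [0.5] * 4,
         "degree": [12, 11, 10, 9], "core": [11, 10, 9, 8]}
    )
    assert h.select_core_genes(topo, 2) == ["A", "B", "C"]
    same = topo.assign(core=7)
    assert set(h.select_core_genes(same, 2)) == set("ABCD")
    assert h.select_core_genes(topo.iloc[0:0], 2) == []
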