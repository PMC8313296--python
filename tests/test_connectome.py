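"""Spatial cell graphs and information-transfer loss under node removal."""

import itertools

import networkx as nx
import numpy as np
import pytest

from osteoatlas.classify import CellRecord
from osteoatlas.connectome import (
    CellGraph,
    build_graph,
    compare_strategies,
    information_transfer,
    node_removal_curve,
)
from osteoatlas.detect import Detection


def _cell(x_um, y_um, status="viable"):
    det = Detection(X=x_um, Y=y_um, W=96, H=96, p=0.9, C=status)
    return CellRecord(
        detection=det, n_processes=4 if status == "viable" else 1, status=status,
        physical_center_um=(x_um, y_um),
    )


def _graph_of(g: nx.Graph) -> CellGraph:
    return CellGraph(graph=g)


# ---------------------------------------------------------------- build_graph
def test_empty_graph():
    cg = build_graph([])
    assert cg.n_nodes == 0 and cg.n_edges == 0
    assert information_transfer(cg) == 0.0


def test_link_radius_rule():
    near = build_graph([_cell(0, 0), _cell(50, 0)], link_radius_um=60)
    far = build_graph([_cell(0, 0), _cell(70, 0)], link_radius_um=60)
    assert near.n_edges == 1
    assert far.n_edges == 0


def test_regular_grid_interior_degree():
    """10x10 grid at 50 um spacing, radius 60: interior nodes have degree 4."""
    cells = [_cell(50.0 * i, 50.0 * j) for i in range(10) for j in range(10)]
    cg = build_graph(cells, link_radius_um=60, max_degree=12)
    degrees = dict(cg.graph.degree())
    interior = [n for n, d in cg.graph.nodes(data=True)
                if 50 <= d["pos"][0] <= 400 and 50 <= d["pos"][1] <= 400]
    assert all(degrees[n] == 4 for n in interior)


def test_max_degree_mutual_pruning():
    # hub with 6 spokes within radius, max_degree 3: hub keeps 3 nearest.
    cells = [_cell(0, 0)] + [_cell(10 + i, 0.01 * i) for i in range(6)]
    cg = build_graph(cells, link_radius_um=60, max_degree=3)
    assert all(d <= 3 for _, d in cg.graph.degree())


def test_graph_is_simple_with_no_self_edges():
    cells = [_cell(i * 10.0, 0) for i in range(5)]
    cg = build_graph(cells, link_radius_um=100)
    assert all(u != v for u, v in cg.graph.edges())


# ------------------------------------------------------- information_transfer
def test_efficiency_reference_values():
    complete = _graph_of(nx.complete_graph(5))
    assert information_transfer(complete) == pytest.approx(1.0)
    edgeless = _graph_of(nx.empty_graph(6))
    assert information_transfer(edgeless) == 0.0
    path3 = _graph_of(nx.path_graph(3))
    assert information_transfer(path3) == pytest.approx((1 + 1 + 0.5) / 3)


def _floyd_warshall_efficiency(g: nx.Graph) -> float:
    """Independent brute force: dense Floyd-Warshall over ordered pairs."""
    nodes = list(g.nodes())
    n = len(nodes)
    if n < 2:
        return 0.0
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges():
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum()) / (n * (n - 1))


def test_efficiency_matches_brute_force_on_random_graphs(rng):
    """Agreement with all-pairs Floyd-Warshall on 200 random <= 8-node graphs."""
    for _ in range(200):
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.1, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        assert information_transfer(_graph_of(g)) == pytest.approx(
            _floyd_warshall_efficiency(g)
        )


# ---------------------------------------------------------- node_removal_curve
def _random_geometric_cellgraph(n, seed, pyknotic_every=4):
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n):
        status = "pyknotic" if i % pyknotic_every == 0 else "viable"
        cells.append(_cell(float(rng.uniform(0, 200)), float(rng.uniform(0, 200)), status))
    return build_graph(cells, link_radius_um=80)


@pytest.mark.parametrize("strategy", ["random", "pyknotic_first", "degree_targeted"])
def test_curve_endpoints_and_monotonicity(strategy):
    cg = _random_geometric_cellgraph(20, seed=8)
    curve = node_removal_curve(cg, strategy=strategy, steps=10, n_replicates=20, seed=3)
    assert curve.transfer[0] == pytest.approx(1.0)
    assert curve.transfer[-1] == pytest.approx(0.0)
    # original-pair-count normalization makes every curve non-increasing
    assert np.all(np.diff(curve.transfer) <= 1e-12)
    assert np.all((0 <= curve.transfer) & (curve.transfer <= 1))


def test_curve_deterministic_for_fixed_seed():
    cg = _random_geometric_cellgraph(15, seed=2)
    c1 = node_removal_curve(cg, "random", steps=5, n_replicates=10, seed=7)
    c2 = node_removal_curve(cg, "random", steps=5, n_replicates=10, seed=7)
    np.testing.assert_array_equal(c1.transfer, c2.transfer)
    np.testing.assert_array_equal(c1.std, c2.std)


def test_star_graph_hub_removal_kills_transfer():
    """Degree-targeted attack on a star removes the hub first: transfer -> 0."""
    n = 8
    star = nx.star_graph(n - 1)  # node 0 is the hub
    cg = _graph_of(star)
    curve = node_removal_curve(cg, "degree_targeted", steps=n, n_replicates=1, seed=0)
    assert curve.transfer[0] == pytest.approx(1.0)
    assert curve.transfer[1] == pytest.approx(0.0)


def test_pyknotic_first_reduces_to_random_when_all_viable():
    cells = [_cell(float(10 * i), 0.0, "viable") for i in range(12)]
    cg = build_graph(cells, link_radius_um=25)
    a = node_removal_curve(cg, "pyknotic_first", steps=6, n_replicates=8, seed=4)
    b = node_removal_curve(cg, "random", steps=6, n_replicates=8, seed=4)
    np.testing.assert_array_equal(a.transfer, b.transfer)


def test_targeted_attack_no_more_robust_than_random(rng):
    """Degree-targeted AUC <= random AUC in >= 95 of 100 seeded trials."""
    wins = 0
    for trial in range(100):
        g = nx.gnp_random_graph(24, 0.15, seed=trial)
        nx.set_node_attributes(g, "viable", "status")
        cg = _graph_of(g)
        rep = compare_strategies(cg, seed=trial, steps=8, n_replicates=3)
        if rep.auc["degree_targeted"] <= rep.auc["random"] + 1e-9:
            wins += 1
    assert wins >= 95


def test_compare_strategies_reports_all():
    cg = _random_geometric_cellgraph(16, seed=5)
    rep = compare_strategies(cg, seed=1, steps=6, n_replicates=5)
    assert set(rep.auc) == {"random", "pyknotic_first", "degree_targeted"}
    assert rep.ordering == sorted(rep.auc, key=lambda s: -rep.auc[s])


def test_graph_io(tmp_path):
    cg = _random_geometric_cellgraph(10, seed=9)
    cg.write_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
    cg.write_graphml(tmp_path / "graph.graphml")
    import pandas as pd

    nodes = pd.read_csv(tmp_path / "nodes.csv")
    edges = pd.read_csv(tmp_path / "edges.csv")
    assert len(nodes) == cg.n_nodes and len(edges) == cg.n_edges
    back = nx.read_graphml(tmp_path / "graph.graphml")
    assert back.number_of_nodes() == cg.n_nodes
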