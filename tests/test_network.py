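"""Network construction, module detection, robustness, identity suite."""

import numpy as np
import pandas as pd
import pytest

from rarecycle import (
    NetworkConfig,
    build_network,
    detect_modules,
    read_network,
    robustness,
    spearman_matrix,
    topology_summary,
    write_network,
)
from rarecycle.network import CooccurrenceNetwork
from rarecycle.tables import OTUTable

from conftest import make_random_network


def _table(counts) -> OTUTable:
    counts = np.atleast_2d(counts)
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(counts.shape[0])],
        columns=[f"o{j}" for j in range(counts.shape[1])],
    )
    return OTUTable(counts=frame, crop=pd.Series("x", index=frame.index))


def _complete(n: int, r: float = 0.9) -> CooccurrenceNetwork:
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], r, 0.01) for i in range(n) for j in range(i + 1, n)
    ]
    return CooccurrenceNetwork.from_edges(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------

def test_spearman_comonotone_pairs():
    counts = np.column_stack([np.arange(1, 7), np.arange(1, 7) ** 2, 7 - np.arange(1, 7)])
    r, p = spearman_matrix(_table(counts))
    assert r.iloc[0, 1] == pytest.approx(1.0)
    assert r.iloc[0, 2] == pytest.approx(-1.0)
    assert p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_spearman_formula_oracle_n6():
    from scipy.stats import rankdata

    rng = np.random.default_rng(0)
    x = rng.permutation(6) + 1
    y = rng.permutation(6) + 1
    r, _ = spearman_matrix(_table(np.column_stack([x, y]) * 10))
    d = rankdata(x) - rankdata(y)
    expected = 1 - 6 * (d**2).sum() / (6 * 35)
    assert r.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


def test_spearman_constant_column_missing():
    counts = np.column_stack([np.arange(1, 7), np.full(6, 5)])
    with pytest.warns(UserWarning, match="constant"):
        r, p = spearman_matrix(_table(counts))
    assert np.isnan(r.iloc[0, 1]) and np.isnan(p.iloc[0, 1])


def test_spearman_needs_four_samples():
    with pytest.raises(ValueError, match="four samples"):
        spearman_matrix(_table(np.ones((3, 5))))


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def _rp(rv, pv):
    ids = [f"o{i}" for i in range(len(rv))]
    return pd.DataFrame(rv, index=ids, columns=ids), pd.DataFrame(pv, index=ids, columns=ids)


def test_edge_kept_and_dropped_by_thresholds():
    rv = np.array([[1.0, 0.61], [0.61, 1.0]])
    r, p = _rp(rv, np.array([[0.0, 0.01], [0.01, 0.0]]))
    assert build_network(r, p).n_edges == 1
    r, p = _rp(rv, np.array([[0.0, 0.06], [0.06, 0.0]]))
    with pytest.warns(UserWarning, match="empty"):
        assert build_network(r, p).n_edges == 0


def test_strict_inequality_at_r_min():
    r, p = _rp(np.array([[1.0, 0.60], [0.60, 1.0]]), np.zeros((2, 2)))
    with pytest.warns(UserWarning, match="empty"):
        assert build_network(r, p).n_edges == 0


def test_edge_count_monotone_in_r_min():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 60, size=(10, 30))
    r, p = spearman_matrix(_table(counts + 1))
    previous = np.inf
    for r_min in (0.3, 0.5, 0.7, 0.9):
        net = build_network(r, p, NetworkConfig(r_min=r_min, alpha=0.5))
        assert net.n_edges <= previous
        previous = net.n_edges


def test_isolated_nodes_dropped():
    rv = np.eye(3)
    rv[0, 1] = rv[1, 0] = 0.9
    r, p = _rp(rv, np.where(np.eye(3, dtype=bool), 0.0, 0.001))
    net = build_network(r, p)
    assert net.nodes == ["o0", "o1"]


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def test_two_cliques_two_modules():
    a = _complete(6)
    edges = list(a.edges) + [
        (f"m{i:02d}", f"m{j:02d}", 0.9, 0.01) for i in range(6) for j in range(i + 1, 6)
    ]
    edges.append(("n00", "m00", 0.7, 0.01))  # single bridge
    nodes = a.nodes + [f"m{i:02d}" for i in range(6)]
    net = CooccurrenceNetwork.from_edges(nodes=nodes, edges=edges)
    membership, q = detect_modules(net, seed=0)
    assert len(set(membership.values())) == 2
    assert q > 0.3


def test_complete_graph_single_module():
    membership, _ = detect_modules(_complete(8), seed=0)
    assert len(set(membership.values())) == 1


def test_modules_deterministic():
    net = make_random_network(seed=2)
    m1, q1 = detect_modules(net, seed=3)
    m2, q2 = detect_modules(net, seed=3)
    assert m1 == m2 and q1 == q2


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

def test_complete_graph_robustness_exact():
    assert robustness(_complete(20), 0.5, n_reps=50, seed=0) == pytest.approx(0.5)


def test_edgeless_graph_robustness():
    net = CooccurrenceNetwork(nodes=[f"n{i}" for i in range(10)], edges=[])
    assert robustness(net, 0.5, n_reps=20, seed=0) == pytest.approx(1 / 10)


def test_star_less_robust_than_complete():
    n = 20
    star = CooccurrenceNetwork.from_edges(
        nodes=[f"n{i:02d}" for i in range(n)],
        edges=[(f"n00", f"n{i:02d}", 0.9, 0.01) for i in range(1, n)],
    )
    assert robustness(star, 0.5, n_reps=200, seed=1) < robustness(
        _complete(n), 0.5, n_reps=200, seed=1
    )


def test_robustness_monotone_in_removal_fraction():
    net = make_random_network(seed=4, n_max=14, p=0.5)
    values = [
        robustness(net, f, n_reps=300, seed=5) for f in (0.2, 0.4, 0.6, 0.8)
    ]
    assert all(a >= b - 0.02 for a, b in zip(values, values[1:]))


def test_robustness_bad_fraction():
    with pytest.raises(ValueError, match="removal_fraction"):
        robustness(_complete(5), 1.5)


# ---------------------------------------------------------------------------
# Topology summary
# ---------------------------------------------------------------------------

def test_triangle_metrics():
    net = _complete(3)
    s = topology_summary(net, seed=0)
    assert s.transitivity == 1.0
    assert s.average_clustering_coefficient == 1.0
    assert s.density == 1.0
    assert s.diameter == 1.0


def test_identity_suite_on_built_network(desk_coupled):
    from rarecycle import prevalence_filter_top

    sub = desk_coupled.bacteria.subset_samples(
        desk_coupled.bacteria.crop.index[desk_coupled.bacteria.crop == "maize"]
    )
    kept = prevalence_filter_top(sub, 0.5)
    r, p = spearman_matrix(kept)
    net = build_network(r, p)
    s = topology_summary(net, seed=0)
    assert s.average_degree * s.node_num == pytest.approx(2 * s.edge_num)
    assert s.density * (s.node_num - 1) == pytest.approx(s.average_degree)
    assert s.frac_positive + s.frac_negative == pytest.approx(1.0)
    for edge in net.edges:
        assert abs(edge[2]) > 0.6 and edge[3] < 0.05


def test_graphml_round_trip_reproduces_topology(tmp_path):
    net = make_random_network(seed=6, n_max=14, p=0.5)
    s1 = topology_summary(net, seed=7)
    back = read_network(write_network(net, tmp_path / "n.graphml"))
    s2 = topology_summary(back, seed=7)
    assert s1.as_dict() == s2.as_dict()
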