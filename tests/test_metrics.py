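"""Centrality, density, assortativity and group-connection measures."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_events, make_static

from trophnet.metrics import (
    assortativity_nominal,
    assortativity_numeric,
    betweenness,
    degree_strength,
    edge_density,
    edge_density_from_counts,
    eigenvector_centrality,
    group_connection_summary,
    individual_target_connections,
)
from trophnet.networks import build_static_network
from trophnet.synthetic import ColonyConfig, generate_colony


# --- degree / strength -----------------------------------------------------


def test_degree_strength_example():
    net = make_static([("A", "B", 2, 7), ("B", "A", 1, 2)])
    table = degree_strength(net)
    a = table.loc["A"]
    assert a["donations"] == 2 and a["receptions"] == 1
    assert a["time_as_donor"] == 7 and a["time_as_receiver"] == 2
    assert a["exchanges_total"] == 3 and a["time_total"] == 9


def test_degree_strength_flow_conservation(rng):
    _, events, _ = generate_colony(ColonyConfig(), rng)
    net = build_static_network(events)
    table = degree_strength(net)
    assert table["donations"].sum() == len(events)
    assert table["receptions"].sum() == len(events)
    assert (table["exchanges_total"] ==
            table["receptions"] + table["donations"]).all()
    assert np.allclose(table["time_total"],
                       table["time_as_receiver"] + table["time_as_donor"])


def test_distinct_partner_variant():
    net = make_static([("A", "B", 5, 50), ("A", "C", 1, 3)])
    table = degree_strength(net, distinct_partners=True)
    assert table.loc["A", "donations"] == 2


# --- betweenness -----------------------------------------------------------


def _betweenness_oracle(g: nx.DiGraph) -> dict:
    """Exhaustive shortest-path enumeration on a small digraph."""
    nodes = list(g.nodes)
    bc = {v: 0.0 for v in nodes}

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in g.successors(node):
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    for s, t in itertools.permutations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            bc[v] += through / len(sp)
    return bc


def test_betweenness_directed_path():
    net = make_static([("A", "B", 1, 3), ("B", "C", 1, 3)])
    bc = betweenness(net)
    assert bc["B"] == 1.0 and bc["A"] == 0.0 and bc["C"] == 0.0


def test_betweenness_complete_triangle_all_zero():
    edges = [(u, v, 1, 3) for u, v in itertools.permutations("ABC", 2)]
    net = make_static(edges)
    assert (betweenness(net) == 0).all()


def test_betweenness_matches_enumeration_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(3, 7))
        pairs = list(itertools.permutations(range(n), 2))
        k = int(rng.integers(2, min(10, len(pairs)) + 1))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
        net = make_static([(str(u), str(v), 1, 3) for u, v in chosen])
        expected = _betweenness_oracle(net.graph)
        got = betweenness(net)
        for v in net.nodes():
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


def test_weighted_betweenness_uses_inverse_duration():
    # A->C direct (short exchange) vs A->B->C (two long exchanges):
    # with 1/duration lengths the two-hop route is shorter, so B lies
    # on the unique shortest path.
    net = make_static([("A", "C", 1, 1), ("A", "B", 1, 100), ("B", "C", 1, 100)])
    assert betweenness(net, use_weights=True)["B"] == 1.0
    assert betweenness(net, use_weights=False)["B"] == 0.0


# --- eigenvector -----------------------------------------------------------


def _eigen_oracle(net):
    """Dense eigen-decomposition of the symmetrized weighted adjacency."""
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, d in net.graph.edges(data=True):
        a[index[u], index[v]] += d["total_duration"]
    a = a + a.T
    vals, vecs = np.linalg.eigh(a)
    lead = np.abs(vecs[:, np.argmax(vals)])
    return dict(zip(nodes, lead / lead.max()))


def test_eigenvector_star():
    net = make_static([("hub", f"leaf{i}", 1, 5) for i in range(3)])
    ev = eigenvector_centrality(net)
    assert ev["hub"] == pytest.approx(1.0)
    leaves = ev[[f"leaf{i}" for i in range(3)]]
    assert leaves.nunique() == 1 and (leaves < 1).all()


def test_eigenvector_two_identical_dyads_symmetric():
    net = make_static([("A", "B", 1, 5), ("C", "D", 1, 5)])
    ev = eigenvector_centrality(net)
    assert ev["A"] == pytest.approx(ev["B"])
    assert ev["C"] == pytest.approx(ev["D"])


def test_eigenvector_matches_dense_decomposition(rng):
    for _ in range(20):
        n = 6
        pairs = list(itertools.permutations(range(n), 2))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=10, replace=False)]
        net = make_static([
            (str(u), str(v), 1, float(rng.uniform(2, 100))) for u, v in chosen
        ])
        expected = _eigen_oracle(net)
        got = eigenvector_centrality(net)
        for v in net.nodes():
            assert got[v] == pytest.approx(expected[v], abs=1e-6)


def test_eigenvector_invariant_under_weight_scaling(rng):
    pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
    weights = rng.uniform(2, 50, size=len(pairs))
    net1 = make_static([(u, v, 1, w) for (u, v), w in zip(pairs, weights)])
    net2 = make_static([(u, v, 1, 7.3 * w) for (u, v), w in zip(pairs, weights)])
    ev1, ev2 = eigenvector_centrality(net1), eigenvector_centrality(net2)
    assert np.allclose(ev1.values, ev2.values, atol=1e-6)


def test_eigenvector_requires_an_edge():
    net = make_static([])
    with pytest.raises(ValueError):
        eigenvector_centrality(net)


# --- density ---------------------------------------------------------------


def test_density_complete_digraph():
    edges = [(u, v, 1, 3) for u, v in itertools.permutations("ABCD", 2)]
    assert edge_density(make_static(edges)) == 1.0


def test_density_undefined_below_two_nodes():
    with pytest.raises(ValueError):
        edge_density_from_counts(1, 0)


def test_density_increases_with_new_edge():
    net1 = make_static([("A", "B", 1, 3), ("B", "C", 1, 3)])
    net2 = make_static([("A", "B", 1, 3), ("B", "C", 1, 3), ("C", "A", 1, 3)])
    assert edge_density(net2) > edge_density(net1)


# --- assortativity ---------------------------------------------------------


def _nominal_oracle(edges, labels):
    """Mixing-matrix formula computed independently from tabulated counts."""
    cats = sorted({labels[u] for u, v in edges} | {labels[v] for u, v in edges})
    k = len(cats)
    m = np.zeros((k, k))
    for u, v in edges:
        m[cats.index(labels[u]), cats.index(labels[v])] += 1
    e = m / m.sum()
    a, b = e.sum(1), e.sum(0)
    return (np.trace(e) - a @ b) / (1 - a @ b)


def test_nominal_perfect_within_category():
    net = make_static([("a1", "a2", 1, 3), ("b1", "b2", 1, 3)])
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    assert assortativity_nominal(net, labels) == pytest.approx(1.0)


def test_nominal_perfect_bipartite_mixing():
    net = make_static([("a1", "b1", 1, 3), ("a2", "b2", 1, 3),
                       ("b1", "a2", 1, 3), ("b2", "a1", 1, 3)])
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    assert assortativity_nominal(net, labels) == pytest.approx(-1.0)


def test_nominal_single_category_undefined():
    net = make_static([("a1", "a2", 1, 3)])
    with pytest.raises(ValueError):
        assortativity_nominal(net, {"a1": "A", "a2": "A"})


def test_nominal_matches_mixing_formula_and_networkx(rng):
    for _ in range(20):
        n = 10
        pairs = list(itertools.permutations(range(n), 2))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=15, replace=False)]
        labels = {str(i): str(rng.choice(["X", "Y", "Z"])) for i in range(n)}
        net = make_static([(str(u), str(v), 1, 3) for u, v in chosen])
        edges = [(str(u), str(v)) for u, v in chosen]
        used = {l for uv in edges for l in (labels[uv[0]], labels[uv[1]])}
        if len(used) < 2:
            continue
        r = assortativity_nominal(net, labels)
        assert r == pytest.approx(_nominal_oracle(edges, labels), abs=1e-12)
        g = net.graph.copy()
        nx.set_node_attributes(g, labels, "cat")
        r_nx = nx.attribute_assortativity_coefficient(g, "cat")
        assert r == pytest.approx(r_nx, abs=1e-9)


def test_nominal_invariant_under_relabeling(rng):
    net = make_static([("0", "1", 1, 3), ("1", "2", 1, 3), ("2", "3", 1, 3),
                       ("3", "0", 1, 3), ("0", "2", 1, 3)])
    labels = {"0": "X", "1": "Y", "2": "X", "3": "Y"}
    renamed = {k: {"X": "ocelot", "Y": "walrus"}[v] for k, v in labels.items()}
    assert assortativity_nominal(net, labels) == pytest.approx(
        assortativity_nominal(net, renamed)
    )


def test_numeric_equal_valued_edges():
    net = make_static([("a1", "a2", 1, 3), ("b1", "b2", 1, 3)])
    values = {"a1": 2.0, "a2": 2.0, "b1": 30.0, "b2": 30.0}
    assert assortativity_numeric(net, values) == pytest.approx(1.0)


def test_numeric_matches_direct_correlation():
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"),
             ("a", "c"), ("b", "d"), ("c", "a"), ("d", "b")]
    values = {"a": 2.0, "b": 9.0, "c": 16.0, "d": 30.0}
    net = make_static([(u, v, 1, 3) for u, v in edges])
    x = np.array([values[u] for u, v in edges])
    y = np.array([values[v] for u, v in edges])
    expected = np.corrcoef(x, y)[0, 1]
    assert assortativity_numeric(net, values) == pytest.approx(expected)


def test_numeric_zero_variance_undefined():
    net = make_static([("a", "b", 1, 3), ("b", "a", 1, 3)])
    with pytest.raises(ValueError):
        assortativity_numeric(net, {"a": 5.0, "b": 5.0})


def test_numeric_near_zero_when_values_independent(rng):
    """Values assigned independently of topology give |r| < 0.1 nearly always."""
    hits = 0
    n_runs = 20
    for _ in range(n_runs):
        n = 60
        pairs = list(itertools.permutations(range(n), 2))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=500, replace=False)]
        values = {str(i): float(rng.normal()) for i in range(n)}
        net = make_static([(str(u), str(v), 1, 3) for u, v in chosen])
        if abs(assortativity_numeric(net, values)) < 0.1:
            hits += 1
    assert hits >= int(0.9 * n_runs)


# --- group connections -----------------------------------------------------


def test_group_summary_no_edges_all_zero():
    net = make_static([("a", "b", 1, 3)])
    summary = group_connection_summary(net, {"a"}, set())
    assert (summary == 0).all()


def test_group_summary_single_donation_to_queen():
    net = make_static([("f", "queen", 1, 5)])
    summary = group_connection_summary(net, {"f"}, {"queen"})
    assert summary["exchanges_as_donor"] == 1
    assert summary["time_as_donor"] == 5
    assert summary["exchanges_as_receiver"] == 0
    assert summary["time_as_receiver"] == 0


def test_group_summary_rejects_overlap():
    net = make_static([("a", "b", 1, 3)])
    with pytest.raises(ValueError, match="overlap"):
        group_connection_summary(net, {"a"}, {"a", "b"})


def test_group_summary_matches_raw_event_scan(rng):
    _, events, _ = generate_colony(ColonyConfig(), rng)
    net = build_static_network(events)
    nodes = sorted(net.nodes())
    focal = set(nodes[:40])
    targets = set(nodes[40:80])
    summary = group_connection_summary(net, focal, targets)
    don = [e for e in events if e.donor_id in focal and e.receiver_id in targets]
    rec = [e for e in events if e.receiver_id in focal and e.donor_id in targets]
    assert summary["exchanges_as_donor"] == len(don)
    assert summary["exchanges_as_receiver"] == len(rec)
    assert summary["time_as_donor"] == pytest.approx(sum(e.duration for e in don))
    assert summary["time_as_receiver"] == pytest.approx(sum(e.duration for e in rec))
    assert summary["exchanges"] == len(don) + len(rec)


def test_individual_connections_split_by_direction():
    net = make_static([("f", "q", 2, 8), ("y", "f", 1, 4), ("f", "x", 1, 9)])
    table = individual_target_connections(net, ["f"], {"q", "y"})
    row = table.loc["f"]
    assert row["exchanges_as_donor"] == 2 and row["time_as_donor"] == 8
    assert row["exchanges_as_receiver"] == 1 and row["time_as_receiver"] == 4
    assert row["exchanges"] == 3 and row["time_total"] == 12
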