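"""Network measures for static trophallaxis networks.

Covers the measure suite used in the colony comparisons: degree and
strength split by direction (event counts and summed durations),
directed shortest-path betweenness, eigenvector centrality on the
(symmetrized, duration-weighted) adjacency, edge density, and
assortativity in both its nominal (categorical) and numeric forms,
plus summaries of the direct connections between two node sets (for
the queen-and-young-workers comparison).

Degree-type measures count discrete exchange events (multigraph
semantics) rather than distinct partners, because per-individual tallies
of "total nectar exchanges" are event counts; a distinct-partner variant
is available via ``distinct_partners=True``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .networks import StaticNetwork

#: Order of the per-node measure columns in :func:`degree_strength`.
DEGREE_STRENGTH_COLUMNS = (
    "exchanges_total",
    "receptions",
    "donations",
    "time_total",
    "time_as_receiver",
    "time_as_donor",
)


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration cap."""


def degree_strength(net: StaticNetwork, distinct_partners: bool = False) -> pd.DataFrame:
    """Per-node directed degree (event counts) and strength (seconds).

    ``receptions``/``donations`` sum incoming/outgoing event counts;
    ``time_as_receiver``/``time_as_donor`` sum incoming/outgoing
    durations.  Totals are the sum of the two directions.  With
    ``distinct_partners=True`` the count columns tally distinct ordered
    partners instead of discrete events.
    """
    g = net.graph
    rows = {}
    for node in g.nodes:
        recv_n = recv_t = don_n = don_t = 0.0
        for _, _, data in g.in_edges(node, data=True):
            recv_n += 1 if distinct_partners else data["n_events"]
            recv_t += data["total_duration"]
        for _, _, data in g.out_edges(node, data=True):
            don_n += 1 if distinct_partners else data["n_events"]
            don_t += data["total_duration"]
        rows[node] = (recv_n + don_n, recv_n, don_n,
                      recv_t + don_t, recv_t, don_t)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(DEGREE_STRENGTH_COLUMNS))
    return df.sort_index()


def betweenness(net: StaticNetwork, use_weights: bool = False) -> pd.Series:
    """Directed shortest-path betweenness (raw path counts, unnormalized).

    Unweighted by default.  With ``use_weights=True`` the edge length is
    the reciprocal of the total exchange duration, so longer (stronger)
    exchanges make shorter distances.
    """
    g = net.graph
    weight = None
    if use_weights:
        g = g.copy()
        for u, v, data in g.edges(data=True):
            data["distance"] = 1.0 / data["total_duration"]
        weight = "distance"
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return pd.Series(bc).sort_index()


def eigenvector_centrality(
    net: StaticNetwork,
    treat_as_undirected: bool = True,
    use_weights: bool = True,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> pd.Series:
    """Principal-eigenvector centrality scores, scaled so the max is 1.

    By default the directed graph is symmetrized (A + Aᵀ on duration
    weights) before extracting the leading eigenvector: sparse directed
    trophallaxis graphs have an almost empty strongly connected core on
    which a purely directed eigenvector collapses to zero.  Power
    iteration runs on A + I (the identity shift leaves eigenvectors
    unchanged but removes the period-2 oscillation bipartite components
    would otherwise cause) to a relative tolerance of ``tol``.  In a
    disconnected network the scores concentrate on the component(s)
    whose spectral radius is largest; weaker components decay to 0.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = data["total_duration"] if use_weights else 1.0
        a[index[u], index[v]] += w
    if treat_as_undirected:
        a = a + a.T

    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w = a @ v + v
        top = w.max()
        if top == 0:
            raise ValueError("adjacency has no positive entries")
        w /= top
        if np.max(np.abs(w - v)) <= tol * np.max(np.abs(w)):
            v = w
            break
        v = w
    else:
        raise ConvergenceError(
            f"power iteration did not converge within {max_iter} iterations"
        )
    v = v / v.max()
    return pd.Series(v, index=nodes)


def edge_density_from_counts(n_nodes: int, n_edges: int) -> float:
    """Directed edge density: distinct ordered pairs over N(N-1)."""
    if n_nodes < 2:
        raise ValueError("edge density is undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1))


def edge_density(net: StaticNetwork) -> float:
    """Density of the static network (distinct ordered pairs basis)."""
    return edge_density_from_counts(net.n_nodes, net.n_edges)


def _edge_weight_iter(net: StaticNetwork, weighted: bool):
    for u, v, data in net.graph.edges(data=True):
        yield u, v, (data["n_events"] if weighted else 1.0)


def assortativity_nominal(
    net: StaticNetwork,
    labels: Mapping,
    weighted: bool = False,
) -> float:
    """Newman's nominal assortativity coefficient on the edge mixing matrix.

    ``r = (Σᵢ eᵢᵢ − Σᵢ aᵢ bᵢ) / (1 − Σᵢ aᵢ bᵢ)`` where ``e`` is the
    normalized category mixing matrix over directed edges, and ``a``,
    ``b`` its row and column sums.  Edges whose endpoints both carry a
    label are counted once per distinct ordered pair by default, or
    weighted by event multiplicity with ``weighted=True``.  Raises if
    fewer than two categories occur among the counted edges.
    """
    cats: dict = {}
    entries = []
    for u, v, w in _edge_weight_iter(net, weighted):
        if u not in labels or v not in labels:
            continue
        cu, cv = labels[u], labels[v]
        for c in (cu, cv):
            if c not in cats:
                cats[c] = len(cats)
        entries.append((cats[cu], cats[cv], w))
    if not entries:
        raise ValueError("no edges with labeled endpoints")
    if len(cats) < 2:
        raise ValueError(
            "nominal assortativity is undefined with a single category"
        )
    k = len(cats)
    e = np.zeros((k, k))
    for i, j, w in entries:
        e[i, j] += w
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    denom = 1.0 - ab
    if denom == 0.0:
        raise ValueError("assortativity undefined: degenerate mixing matrix")
    return (float(np.trace(e)) - ab) / denom


def assortativity_numeric(
    net: StaticNetwork,
    values: Mapping,
    weighted: bool = False,
) -> float:
    """Pearson correlation of (donor value, receiver value) over edges.

    Nodes without a value (e.g. unknown age) are excluded: edges with an
    unvalued endpoint do not contribute.  With ``weighted=True`` each
    edge contributes with frequency equal to its event count.  Raises if
    either endpoint vector has zero variance.
    """
    xs, ys, ws = [], [], []
    for u, v, w in _edge_weight_iter(net, weighted):
        if u not in values or v not in values:
            continue
        xs.append(float(values[u]))
        ys.append(float(values[v]))
        ws.append(w)
    if len(xs) < 2:
        raise ValueError("numeric assortativity needs at least two valued edges")
    x = np.asarray(xs)
    y = np.asarray(ys)
    w = np.asarray(ws)
    cov = np.cov(np.vstack([x, y]), fweights=w.astype(int) if weighted else None)
    if cov[0, 0] == 0 or cov[1, 1] == 0:
        raise ValueError("numeric assortativity undefined: zero variance")
    return float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))


#: Column order of the per-node group-connection table.
CONNECTION_COLUMNS = (
    "exchanges",
    "exchanges_as_receiver",
    "exchanges_as_donor",
    "time_total",
    "time_as_receiver",
    "time_as_donor",
)


def individual_target_connections(
    net: StaticNetwork,
    nodes: Iterable,
    targets: Iterable,
) -> pd.DataFrame:
    """Per-node direct connections to a target node set.

    For each node, counts and durations of its exchanges whose other
    endpoint lies in ``targets``, split by the node's role in the
    exchange (donor vs receiver).
    """
    g = net.graph
    targets = set(targets)
    rows = {}
    for node in nodes:
        recv_n = recv_t = don_n = don_t = 0.0
        for u, _, data in g.in_edges(node, data=True):
            if u in targets:
                recv_n += data["n_events"]
                recv_t += data["total_duration"]
        for _, v, data in g.out_edges(node, data=True):
            if v in targets:
                don_n += data["n_events"]
                don_t += data["total_duration"]
        rows[node] = (recv_n + don_n, recv_n, don_n,
                      recv_t + don_t, recv_t, don_t)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=list(CONNECTION_COLUMNS))
    return df.sort_index()


def group_connection_summary(
    net: StaticNetwork,
    focal: Iterable,
    targets: Iterable,
) -> pd.Series:
    """Summed focal-group connections to a disjoint target set."""
    focal = set(focal)
    targets = set(targets)
    overlap = focal & targets
    if overlap:
        raise ValueError(
            f"focal and target sets overlap: {sorted(overlap)[:5]}"
        )
    table = individual_target_connections(net, focal, targets)
    if table.empty:
        return pd.Series(0.0, index=list(CONNECTION_COLUMNS))
    return table.sum(axis=0)
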