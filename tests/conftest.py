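import numpy as np
import pytest

from trophnet.events import TrophallaxisEvent
from trophnet.networks import StaticNetwork, build_static_network

import networkx as nx


def make_events(rows, colony="c1"):
    """rows: iterable of (donor, receiver, start, duration)."""
    return [
        TrophallaxisEvent(donor_id=d, receiver_id=r, start_time=t,
                          duration=w, colony_id=colony)
        for d, r, t, w in rows
    ]


def make_static(edges) -> StaticNetwork:
    """edges: iterable of (u, v, n_events, total_duration)."""
    g = nx.DiGraph()
    for u, v, n, w in edges:
        g.add_edge(u, v, n_events=n, total_duration=float(w))
    for node in g.nodes:
        g.nodes[node].setdefault("age_days", None)
        g.nodes[node].setdefault("role", "worker")
        g.nodes[node].setdefault("hygienic", False)
        g.nodes[node].setdefault("group", "other")
    return StaticNetwork(graph=g)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
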