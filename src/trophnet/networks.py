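"""Static and temporal network representations of a trophallaxis log.

The static network is a directed graph whose nodes are exactly the
individuals that took part in at least one (filtered) exchange.  Each
ordered pair (donor, receiver) carries the number of discrete exchanges
(``n_events``) and their summed duration in seconds (``total_duration``).
Node attributes record age, role, hygienic status and the analysis
group: ``hygienic`` (the focal group), ``non_hygienic_middle_aged``
(workers of the reference age cohort, 16 days by default, that were not
coded hygienic), ``queen``, or ``other``.

The temporal network keeps the individual events, chronologically
ordered, so that only time-respecting paths count as transmission
routes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .events import (
    IndividualRecord,
    TrophallaxisEvent,
    ValidationError,
    code_hygienic_status,
)

#: Node group labels used throughout the analysis.
GROUP_FOCAL = "hygienic"
GROUP_REFERENCE = "non_hygienic_middle_aged"
GROUP_QUEEN = "queen"
GROUP_OTHER = "other"

DEFAULT_REFERENCE_AGES = frozenset({16})
DEFAULT_HORIZON_S = 3600.0


@dataclass
class StaticNetwork:
    """Directed, weighted aggregate of an event log (wraps a DiGraph)."""

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list:
        return list(self.graph.nodes)

    def node_attribute(self, name: str) -> dict:
        return dict(self.graph.nodes(data=name))

    def group_nodes(self, group: str) -> list:
        return [n for n, g in self.graph.nodes(data="group") if g == group]


@dataclass(frozen=True)
class TemporalNetwork:
    """Chronologically ordered event sequence over a fixed node set."""

    nodes: tuple
    events: tuple[TrophallaxisEvent, ...]
    horizon: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _group_label(age_days, role, hygienic, reference_ages) -> str:
    if role == "queen":
        return GROUP_QUEEN
    if hygienic:
        return GROUP_FOCAL
    if age_days is not None and age_days in reference_ages:
        return GROUP_REFERENCE
    return GROUP_OTHER


def build_static_network(
    events: Sequence[TrophallaxisEvent],
    roster: Sequence[IndividualRecord] | None = None,
    hygienic: Mapping[str, bool] | None = None,
    reference_ages: Iterable[int] = DEFAULT_REFERENCE_AGES,
) -> StaticNetwork:
    """Aggregate filtered events into a directed, weighted static network.

    Only individuals appearing in at least one event become nodes.
    Individuals absent from the roster are kept with unknown age and
    worker role.  If ``hygienic`` is not given it is derived from the
    roster's act history via :func:`code_hygienic_status`.
    """
    reference_ages = frozenset(reference_ages)
    roster = list(roster) if roster is not None else []
    by_id = {r.id: r for r in roster}
    if hygienic is None:
        hygienic = code_hygienic_status(roster, events) if roster else {}

    g = nx.DiGraph()
    for e in events:
        if g.has_edge(e.donor_id, e.receiver_id):
            data = g[e.donor_id][e.receiver_id]
            data["n_events"] += 1
            data["total_duration"] += e.duration
        else:
            g.add_edge(e.donor_id, e.receiver_id, n_events=1,
                       total_duration=e.duration)

    for node in g.nodes:
        rec = by_id.get(node)
        age = rec.age_days if rec is not None else None
        role = rec.role if rec is not None else "worker"
        flag = bool(hygienic.get(node, False))
        g.nodes[node]["age_days"] = age
        g.nodes[node]["role"] = role
        g.nodes[node]["hygienic"] = flag
        g.nodes[node]["group"] = _group_label(age, role, flag, reference_ages)

    return StaticNetwork(graph=g)


def build_temporal_network(
    events: Sequence[TrophallaxisEvent],
    horizon: float = DEFAULT_HORIZON_S,
) -> TemporalNetwork:
    """Stably sort events by start time into a temporal network.

    Ties in start time keep their input order.  An event starting after
    the observation horizon is a validation error.
    """
    for e in events:
        if e.start_time > horizon:
            raise ValidationError(
                f"event at t={e.start_time} exceeds horizon {horizon}"
            )
    ordered = tuple(sorted(events, key=lambda e: e.start_time))
    nodes = tuple(sorted({p for e in ordered for p in e.participants()}))
    return TemporalNetwork(nodes=nodes, events=ordered, horizon=horizon)
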