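"""Time-respecting spread simulation on temporal trophallaxis networks.

A simulated infection with perfect transmission starts at a seed
individual and propagates along events in chronological order: once a
participant of an event is infected, the other participant becomes
infected and can transmit at any strictly later event.  Only
time-respecting paths therefore count as transmission routes.  In
``forward`` mode the infection follows the nectar flow (donor infects
receiver); in ``both`` mode (the default) either infected participant
of a mouth-to-mouth contact infects the other.  Event duration plays no
role under perfect transmission.

The per-seed *spread potential* is the fraction of networked
individuals reached by the end of the observation window.  Group
differences in spread potential are tested against a time-permutation
null: event times are shuffled among events (donor, receiver and
duration untouched) and the whole spread analysis is recomputed for
each permuted network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import TemporalNetwork
from .permutation import (
    FOCAL,
    REFERENCE,
    PermutationResult,
    PermutationSpec,
    _make_result,
)

MODES = ("forward", "both")


@dataclass
class SpreadResult:
    """Per-seed reach of a perfect-transmission spread simulation.

    ``table`` has one row per seed node with ``reached_count`` (unique
    individuals reached, seed excluded) and ``reached_fraction`` (count
    over the total number of networked individuals).  ``trajectories``
    maps each seed to its cumulative (event time, count) step curve.
    """

    table: pd.DataFrame
    reached: dict
    trajectories: dict
    mode: str
    n_nodes: int

    @property
    def max_fraction(self) -> float:
        if self.table.empty:
            return 0.0
        return float(self.table["reached_fraction"].max())


def _propagate(
    tnet: TemporalNetwork,
    seeds: Sequence,
    mode: str,
    record: bool = False,
):
    """Single chronological pass propagating all seeds at once.

    Each node carries a bitmask of the seeds whose infection has reached
    it; an event merges masks according to the transmission mode.
    Simultaneous events are processed in stored order, so infection
    acquired at an event is transmissible at any later pass position.
    Returns (counts, reached sets, trajectories) aligned with ``seeds``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    node_set = set(tnet.nodes)
    for s in seeds:
        if s not in node_set:
            raise ValueError(f"seed {s!r} is not a node of the temporal network")

    mask = {v: 0 for v in tnet.nodes}
    for i, s in enumerate(seeds):
        mask[s] |= 1 << i
    counts = [0] * len(seeds)
    reached = [set() for _ in seeds] if record else None
    traj = [[(0.0, 0)] for _ in seeds] if record else None

    for ev in tnet.events:
        d, r = ev.donor_id, ev.receiver_id
        md, mr = mask[d], mask[r]
        if mode == "forward":
            updates = ((r, md & ~mr),)
            mask[r] = mr | md
        else:
            merged = md | mr
            updates = ((r, merged & ~mr), (d, merged & ~md))
            mask[d] = mask[r] = merged
        for node, new in updates:
            while new:
                low = new & -new
                new ^= low
                i = low.bit_length() - 1
                counts[i] += 1
                if record:
                    reached[i].add(node)
                    traj[i].append((ev.start_time, counts[i]))
    return counts, reached, traj


def time_respecting_reach(
    tnet: TemporalNetwork,
    seed,
    mode: str = "both",
) -> SpreadResult:
    """Reach of a perfect-transmission infection seeded at one individual."""
    return spread_analysis(tnet, mode=mode, seeds=[seed])


def spread_analysis(
    tnet: TemporalNetwork,
    mode: str = "both",
    seeds: Sequence | None = None,
) -> SpreadResult:
    """Spread potential of every seed (default: all networked individuals).

    Also exposes the maximum reached fraction over seeds — the "super
    spreader" summary — via :attr:`SpreadResult.max_fraction`.
    """
    if seeds is None:
        seeds = list(tnet.nodes)
    else:
        seeds = list(seeds)
    n = tnet.n_nodes
    counts, reached, traj = _propagate(tnet, seeds, mode, record=True)
    table = pd.DataFrame(
        {
            "reached_count": counts,
            "reached_fraction": [c / n if n else 0.0 for c in counts],
        },
        index=pd.Index(seeds, name="seed"),
    )
    return SpreadResult(
        table=table,
        reached={s: frozenset(r) for s, r in zip(seeds, reached)},
        trajectories={s: list(t) for s, t in zip(seeds, traj)},
        mode=mode,
        n_nodes=n,
    )


def time_shuffle(tnet: TemporalNetwork, rng: np.random.Generator) -> TemporalNetwork:
    """Randomly reassign the multiset of start times among events.

    Donor, receiver and duration stay with their event; only the times
    move.  The resulting event sequence is re-sorted chronologically.
    """
    times = [e.start_time for e in tnet.events]
    perm = rng.permutation(len(times))
    shuffled = [
        replace(e, start_time=times[perm[i]]) for i, e in enumerate(tnet.events)
    ]
    ordered = tuple(sorted(shuffled, key=lambda e: e.start_time))
    return TemporalNetwork(nodes=tnet.nodes, events=ordered, horizon=tnet.horizon)


def _group_fractions_coefficient(
    tnet: TemporalNetwork,
    focal: Sequence,
    reference: Sequence,
    mode: str,
    n_nodes: int,
) -> float:
    seeds = list(focal) + list(reference)
    counts, _, _ = _propagate(tnet, seeds, mode, record=False)
    frac = np.asarray(counts, dtype=float) / n_nodes
    return float(frac[len(focal):].mean() - frac[: len(focal)].mean())


def spread_potential_test(
    tnet: TemporalNetwork,
    labels: Mapping,
    spec: PermutationSpec,
    mode: str = "both",
) -> PermutationResult:
    """Time-permutation test of group differences in spread potential.

    The observed statistic is the group coefficient (reference minus
    focal mean) of the per-seed reached fractions.  The null recomputes
    the full spread analysis on ``n_perm`` time-shuffled networks.
    """
    node_set = set(tnet.nodes)
    focal = sorted(n for n, g in labels.items() if g == FOCAL and n in node_set)
    reference = sorted(
        n for n, g in labels.items() if g == REFERENCE and n in node_set
    )
    if not focal or not reference:
        raise ValueError(
            "both focal and reference groups must be non-empty among "
            "networked individuals"
        )
    n = tnet.n_nodes
    observed = _group_fractions_coefficient(tnet, focal, reference, mode, n)
    rng = np.random.default_rng(spec.seed)
    null = np.empty(spec.n_perm)
    for i in range(spec.n_perm):
        shuffled = time_shuffle(tnet, rng)
        null[i] = _group_fractions_coefficient(shuffled, focal, reference, mode, n)
    return _make_result(observed, null, spec)
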