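"""Colony-level report tables: summaries, group comparisons, assortativity.

Produces the tabular outputs of a full analysis run:

* a colony summary (node/edge counts, density, maximum exchange
  duration, hygienic-worker counts by task with mean +/- SD ages, and
  how many hygienic / reference workers made it into the network);
* the group-comparison table contrasting hygienic workers with
  non-hygienic middle-aged workers over the eight centrality measures
  (sums and medians per group, linear-model coefficient, permutation
  p-value);
* the queen-and-young-workers comparison over the six direct-connection
  measures;
* assortativity tests for hygienic status (nominal) and age (numeric).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import IndividualRecord, TrophallaxisEvent
from .metrics import (
    CONNECTION_COLUMNS,
    DEGREE_STRENGTH_COLUMNS,
    betweenness,
    degree_strength,
    edge_density,
    eigenvector_centrality,
    individual_target_connections,
)
from .networks import GROUP_FOCAL, GROUP_QUEEN, GROUP_REFERENCE, StaticNetwork
from .permutation import (
    FOCAL,
    REFERENCE,
    PermutationResult,
    PermutationSpec,
    assortativity_permutation_test,
    node_permutation_test,
)

#: The eight measures of the centrality comparison, in report order.
CENTRALITY_MEASURES = DEGREE_STRENGTH_COLUMNS + ("betweenness", "eigenvector")


def _spawn_seeds(seed: int | None, n: int) -> list[int | None]:
    """Derive n child seeds (< 2**31) deterministically from one root seed."""
    if seed is None:
        return [None] * n
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def membership_labels(net: StaticNetwork) -> dict:
    """Map networked nodes to focal/reference membership from group labels."""
    out = {}
    for node, group in net.graph.nodes(data="group"):
        if group == GROUP_FOCAL:
            out[node] = FOCAL
        elif group == GROUP_REFERENCE:
            out[node] = REFERENCE
        else:
            out[node] = "other"
    return out


def check_groups(net: StaticNetwork) -> tuple[list, list]:
    """Focal and reference node lists; raises a named error if one is empty."""
    focal = sorted(net.group_nodes(GROUP_FOCAL))
    reference = sorted(net.group_nodes(GROUP_REFERENCE))
    if not focal:
        raise ValueError("no hygienic workers present in the network")
    if not reference:
        raise ValueError(
            "no non-hygienic middle-aged workers present in the network"
        )
    return focal, reference


def colony_summary(
    roster: Sequence[IndividualRecord],
    net: StaticNetwork,
    events: Sequence[TrophallaxisEvent] | None = None,
) -> dict:
    """Summary statistics of one colony network and its hygienic workers.

    Hygienic workers here are all roster individuals with at least one
    observed act (regardless of whether they later entered the network);
    the in-network count uses the coded hygienic flag on networked
    nodes.  Task classes are uncap-only, remove-only and both;
    percentages are of the total hygienic count.  Task age statistics
    cover every performer of that task with a known age.
    """
    performers = [r for r in roster if r.hygienic_acts]
    n_total = len(performers)

    def tasks_of(rec):
        return {a.task for a in rec.hygienic_acts}

    uncap_only = [r for r in performers if tasks_of(r) == {"uncap"}]
    remove_only = [r for r in performers if tasks_of(r) == {"remove"}]
    both = [r for r in performers if tasks_of(r) == {"uncap", "remove"}]

    def pct(k):
        return 100.0 * k / n_total if n_total else float("nan")

    def age_stats(recs, task):
        ages = [r.age_days for r in recs
                if task in tasks_of(r) and r.age_days is not None]
        if not ages:
            return float("nan"), float("nan")
        return float(np.mean(ages)), float(np.std(ages, ddof=1)) if len(ages) > 1 else 0.0

    uncap_mean, uncap_sd = age_stats(performers, "uncap")
    remove_mean, remove_sd = age_stats(performers, "remove")

    hygienic_in_net = net.group_nodes(GROUP_FOCAL)
    reference_in_net = net.group_nodes(GROUP_REFERENCE)

    durations = [e.duration for e in events] if events else [
        d["total_duration"] for _, _, d in net.graph.edges(data=True)
    ]

    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "max_duration_s": max(durations) if durations else float("nan"),
        "density": edge_density(net) if net.n_nodes >= 2 else float("nan"),
        "n_hygienic_total": n_total,
        "n_uncap_only": len(uncap_only),
        "pct_uncap_only": pct(len(uncap_only)),
        "n_remove_only": len(remove_only),
        "pct_remove_only": pct(len(remove_only)),
        "n_both": len(both),
        "pct_both": pct(len(both)),
        "age_uncap_mean": uncap_mean,
        "age_uncap_sd": uncap_sd,
        "age_remove_mean": remove_mean,
        "age_remove_sd": remove_sd,
        "n_hygienic_in_network": len(hygienic_in_net),
        "pct_hygienic_in_network": pct(len(hygienic_in_net)),
        "n_reference_in_network": len(reference_in_net),
    }
    return summary


def _comparison_table(
    values_table: pd.DataFrame,
    measures: Sequence[str],
    focal: Sequence,
    reference: Sequence,
    labels: Mapping,
    net: StaticNetwork,
    n_perm: int,
    seed: int | None,
    alpha_per_tail: float,
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    seeds = _spawn_seeds(seed, len(measures))
    rows = []
    results: dict[str, PermutationResult] = {}
    for measure, child_seed in zip(measures, seeds):
        col = values_table[measure]
        spec = PermutationSpec(n_perm=n_perm, seed=child_seed,
                               alpha_per_tail=alpha_per_tail)
        res = node_permutation_test(
            lambda _net, _col=col: _col.to_dict(), net, labels, spec
        )
        results[measure] = res
        rows.append({
            "measure": measure,
            "focal_sum": float(col.loc[list(focal)].sum()),
            "focal_median": float(col.loc[list(focal)].median()),
            "reference_sum": float(col.loc[list(reference)].sum()),
            "reference_median": float(col.loc[list(reference)].median()),
            "coefficient": res.observed,
            "p_lower": res.p_lower,
            "p_upper": res.p_upper,
            "p_reported": res.p_reported,
            "significant": res.significant,
            "n_perm": res.n_perm,
            "seed": res.seed,
        })
    return pd.DataFrame(rows).set_index("measure"), results


def group_comparison(
    net: StaticNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_per_tail: float = 0.025,
    weighted_betweenness: bool = False,
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    """Hygienic vs non-hygienic middle-aged comparison over 8 measures.

    Six degree/strength measures plus betweenness and eigenvector
    centrality, each tested with a restricted node permutation.
    """
    focal, reference = check_groups(net)
    labels = membership_labels(net)
    table = degree_strength(net)
    table["betweenness"] = betweenness(net, use_weights=weighted_betweenness)
    table["eigenvector"] = eigenvector_centrality(net)
    return _comparison_table(
        table, CENTRALITY_MEASURES, focal, reference, labels, net,
        n_perm, seed, alpha_per_tail,
    )


def queen_young_targets(net: StaticNetwork, young_age: int = 2) -> list:
    """The queen plus the youngest cohort, minus any focal/reference node."""
    g = net.graph
    targets = set(net.group_nodes(GROUP_QUEEN))
    for node, age in g.nodes(data="age_days"):
        if age == young_age and g.nodes[node]["group"] not in (
            GROUP_FOCAL, GROUP_REFERENCE
        ):
            targets.add(node)
    return sorted(targets)


def queen_young_comparison(
    net: StaticNetwork,
    young_age: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_per_tail: float = 0.025,
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    """Direct connections to the queen and youngest workers, by group.

    Per-individual connection counts/durations toward the target set
    are the response values; the restricted node permutation moves the
    hygienic / non-hygienic-middle-aged labels exactly as in the
    centrality comparison.
    """
    focal, reference = check_groups(net)
    labels = membership_labels(net)
    targets = queen_young_targets(net, young_age)
    table = individual_target_connections(net, focal + reference, targets)
    return _comparison_table(
        table, CONNECTION_COLUMNS, focal, reference, labels, net,
        n_perm, seed, alpha_per_tail,
    )


def assortativity_report(
    net: StaticNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha_per_tail: float = 0.025,
) -> tuple[pd.DataFrame, dict[str, PermutationResult]]:
    """Unrestricted permutation tests of hygienic-status and age assortativity.

    Hygienic status uses the nominal coefficient over all networked
    nodes; age uses the numeric coefficient over nodes of known age
    (the number of unknown-age nodes skipped is reported).
    """
    g = net.graph
    hygienic_attr = {n: bool(f) for n, f in g.nodes(data="hygienic")}
    age_attr = {n: a for n, a in g.nodes(data="age_days") if a is not None}
    n_skipped = net.n_nodes - len(age_attr)

    seeds = _spawn_seeds(seed, 2)
    rows = []
    results: dict[str, PermutationResult] = {}
    for name, attr, kind, child_seed, skipped in (
        ("hygienic_status", hygienic_attr, "nominal", seeds[0], 0),
        ("age", age_attr, "numeric", seeds[1], n_skipped),
    ):
        spec = PermutationSpec(n_perm=n_perm, seed=child_seed,
                               alpha_per_tail=alpha_per_tail)
        res = assortativity_permutation_test(net, attr, spec, kind=kind)
        results[name] = res
        row = res.to_row()
        row.update({"attribute": name, "kind": kind, "n_excluded": skipped})
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute"), results
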