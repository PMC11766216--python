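"""Node-permutation significance tests for network measures.

Network measures violate the independence assumptions of classical
tests, so group differences are assessed against a null distribution
built by permuting node labels: shuffling which individuals carry the
"hygienic" vs "non-hygienic middle-aged" label uncouples phenotype from
network position while holding the network structure, the measure
values, and the group sizes fixed.  Restricted permutations shuffle
labels only within the two focal groups; unrestricted permutations
(used for assortativity) shuffle an attribute across all nodes.

The test statistic for group comparisons is the coefficient of a linear
model regressing the measure on group membership, which for a binary
indicator equals the difference of group means.  The reference group is
coded 1 and the focal group 0, so a positive coefficient means the
reference (non-hygienic middle-aged) group has the larger mean.

Significance follows the empirical two-tailed rule: the observed value
is significant when fewer than 2.5% of permuted values fall at or
beyond it in either tail.  Tail proportions use the add-one estimator
(the observed network counts as one permutation) so a p-value of
exactly zero cannot occur; the plain-proportion variant is available
via ``include_observed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Collection, Hashable, Mapping

import numpy as np

from .metrics import assortativity_nominal, assortativity_numeric
from .networks import StaticNetwork

#: Membership labels understood by the group-difference statistic.
FOCAL = "focal"
REFERENCE = "reference"


@dataclass(frozen=True)
class PermutationSpec:
    """Parameters of a permutation test.

    ``restricted_set`` limits the shuffle to a node subset (defaults to
    every node labeled focal or reference).  ``alpha_per_tail`` is the
    per-tail significance level of the two-tailed decision rule.
    """

    n_perm: int = 1000
    restricted_set: tuple | None = None
    seed: int | None = None
    alpha_per_tail: float = 0.025
    include_observed: bool = True

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.alpha_per_tail < 0.5):
            raise ValueError("alpha_per_tail must lie in (0, 0.5)")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, permutation null, tail proportions and verdict."""

    observed: float
    null_values: np.ndarray
    p_lower: float
    p_upper: float
    p_reported: float
    significant: bool
    n_perm: int
    seed: int | None
    alpha_per_tail: float

    def to_row(self) -> dict:
        return {
            "observed": self.observed,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "p_reported": self.p_reported,
            "significant": self.significant,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def group_coefficient(values: Mapping, membership: Mapping) -> float:
    """Linear-model coefficient for a binary group contrast.

    Regressing the measure on a 0/1 indicator (reference = 1, focal = 0)
    gives a slope exactly equal to ``mean(reference) - mean(focal)``,
    which is what this computes.  Nodes labeled anything else are
    ignored.  Raises if either group is empty.
    """
    focal_vals = [float(values[n]) for n, g in membership.items() if g == FOCAL]
    ref_vals = [float(values[n]) for n, g in membership.items() if g == REFERENCE]
    if not focal_vals or not ref_vals:
        raise ValueError("both focal and reference groups must be non-empty")
    return float(np.mean(ref_vals) - np.mean(focal_vals))


def restricted_shuffle(
    labels: Mapping,
    restricted_set: Collection,
    rng: np.random.Generator,
) -> dict:
    """Uniformly permute labels within ``restricted_set``, fixing the rest.

    The multiset of labels inside the restricted set (hence every group
    size) is conserved by construction.
    """
    out = dict(labels)
    nodes = list(restricted_set)
    perm = rng.permutation(len(nodes))
    for i, node in enumerate(nodes):
        out[node] = labels[nodes[perm[i]]]
    return out


def _tail_proportions(
    observed: float, null: np.ndarray, include_observed: bool
) -> tuple[float, float]:
    add = 1 if include_observed else 0
    n = null.size + add
    p_lower = (int(np.count_nonzero(null <= observed)) + add) / n
    p_upper = (int(np.count_nonzero(null >= observed)) + add) / n
    return p_lower, p_upper


def _make_result(observed: float, null: np.ndarray, spec: PermutationSpec) -> PermutationResult:
    p_lower, p_upper = _tail_proportions(observed, null, spec.include_observed)
    p_reported = min(p_lower, p_upper)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_lower=p_lower,
        p_upper=p_upper,
        p_reported=p_reported,
        significant=p_reported < spec.alpha_per_tail,
        n_perm=spec.n_perm,
        seed=spec.seed,
        alpha_per_tail=spec.alpha_per_tail,
    )


def node_permutation_test(
    metric_extractor: Callable[[StaticNetwork], Mapping],
    net: StaticNetwork,
    labels: Mapping,
    spec: PermutationSpec,
) -> PermutationResult:
    """Restricted node-permutation test of a group difference.

    ``metric_extractor`` maps the network to per-node measure values; it
    is evaluated once.  Each permutation shuffles the labels within the
    restricted set (values stay attached to their nodes — the node
    permutation moves phenotype, not position) and recomputes the group
    coefficient.
    """
    values = metric_extractor(net)
    if spec.restricted_set is not None:
        restricted = list(spec.restricted_set)
    else:
        restricted = [n for n, g in labels.items() if g in (FOCAL, REFERENCE)]

    v = np.array([float(values[n]) for n in restricted])
    g = np.array([labels[n] for n in restricted], dtype=object)
    focal_mask = g == FOCAL
    ref_mask = g == REFERENCE
    n_focal = int(focal_mask.sum())
    n_ref = int(ref_mask.sum())
    if n_focal == 0 or n_ref == 0:
        raise ValueError(
            "both focal and reference groups must be non-empty within the "
            "restricted set"
        )
    observed = float(v[ref_mask].mean() - v[focal_mask].mean())

    rng = np.random.default_rng(spec.seed)
    null = np.empty(spec.n_perm)
    size = len(restricted)
    for i in range(spec.n_perm):
        perm = rng.permutation(size)
        gp = g[perm]
        null[i] = v[gp == REFERENCE].mean() - v[gp == FOCAL].mean()
    return _make_result(observed, null, spec)


def assortativity_permutation_test(
    net: StaticNetwork,
    attribute: Mapping,
    spec: PermutationSpec,
    kind: str = "auto",
    weighted: bool = False,
) -> PermutationResult:
    """Unrestricted node-permutation test of attribute assortativity.

    The attribute values are shuffled across all attribute-bearing nodes
    (nodes without a value, e.g. unknown age, stay excluded in both the
    observed and the permuted statistic).  ``kind`` selects the nominal
    or numeric coefficient; ``auto`` treats bool/str attributes as
    nominal and numbers as numeric.
    """
    keys = sorted(attribute)
    if kind == "auto":
        sample = attribute[keys[0]]
        kind = "nominal" if isinstance(sample, (bool, str)) else "numeric"
    if kind == "nominal":
        stat = lambda attr: assortativity_nominal(net, attr, weighted=weighted)
    elif kind == "numeric":
        stat = lambda attr: assortativity_numeric(net, attr, weighted=weighted)
    else:
        raise ValueError(f"unknown assortativity kind {kind!r}")

    observed = stat(attribute)
    vals = [attribute[k] for k in keys]
    rng = np.random.default_rng(spec.seed)
    null = np.empty(spec.n_perm)
    for i in range(spec.n_perm):
        perm = rng.permutation(len(keys))
        shuffled = {keys[j]: vals[perm[j]] for j in range(len(keys))}
        null[i] = stat(shuffled)
    return _make_result(observed, null, spec)
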