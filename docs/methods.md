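# Methods

## Data model and filtering

The observational unit is a single trophallaxis event: donor, receiver,
start time (seconds from the start of filming) and duration (seconds).
Exchanges **under 2 s are dropped** before any analysis — very short
contacts rarely involve nectar transfer — and the boundary is inclusive
(an exchange of exactly 2 s is kept, since only interactions *under*
the threshold are excluded).

Hygienic acts (uncap / remove) carry timestamps on the same clock;
non-positive times mark acts seen during the manual watch that precedes
filming.  A bee is **coded hygienic** iff it performed at least one act
and it is not the case that every one of its interactions started
strictly before its earliest act: a bee whose social life ended before
it ever touched dead brood tells us nothing about post-task behavior.
Ties (an interaction starting exactly at the first act) do not count as
"prior" — strict precedence — and are reported through the logging
system, since the convention is a genuine judgment call on which
reasonable analysts could differ.

Networks contain exactly the individuals that appear in at least one
filtered event.  The static network is a directed graph storing, per
ordered pair, the event count and the summed duration (multigraph
semantics: "total exchanges" counts events, not partners, matching how
per-bee exchange tallies are reported; a distinct-partner variant is
available by flag).  The temporal network is the chronologically sorted
event sequence; ties keep input order.

## Measures

* **Degree/strength**: receptions and donations are incoming/outgoing
  event counts; time as receiver/donor the corresponding summed
  durations.  Flow conservation (Σ donations = Σ receptions = number of
  events) is enforced by tests.
* **Betweenness**: directed, unnormalized shortest-path betweenness
  (raw path counts, so group sums are comparable across colonies).
  Unweighted by default; when duration weighting is requested the edge
  length is `1/total_duration`, because a longer exchange is a stronger
  tie and must yield a *shorter* distance.  Whether the original
  analyses weighted these measures is not documented, so both variants
  exist and the run manifest records the choice.
* **Eigenvector centrality**: computed on the symmetrized
  (`A + Aᵀ`) duration-weighted adjacency and scaled so the maximum
  score is 1.  Sparse directed trophallaxis graphs have an almost-empty
  strongly connected core on which a purely directed eigenvector
  collapses to zero, hence the undirected default (a directed variant
  exists by flag).  The implementation is power iteration on `A + I`
  to relative tolerance 1e-9 with a 10 000-iteration cap; the identity
  shift leaves eigenvectors unchanged while preventing the period-2
  oscillation that bipartite components otherwise cause.  In a
  disconnected graph, scores concentrate on the spectrally dominant
  component(s); weaker components decay toward zero.  Tests check the
  scores against a dense eigendecomposition to 1e-6.
* **Density**: distinct ordered pairs over `N(N−1)`; with the published
  colony summaries (258 edges / 310 nodes and 302 / 354) this
  reproduces the printed 0.003 and 0.002.
* **Assortativity**: the nominal (categorical) coefficient is Newman's
  mixing-matrix formula over directed edges; the numeric form is the
  Pearson correlation of (donor value, receiver value) pairs.  Both
  default to counting each ordered pair once; an event-multiplicity
  weighted variant is flagged.  Unknown-age bees are excluded from age
  assortativity, and the report records how many were skipped.  Single
  category or zero variance raises an explicit error rather than
  returning NaN.

## Permutation inference

Network measures violate the independence assumptions of classical
tests, so all group comparisons use node permutations: labels move,
node positions and measure values stay.  The statistic is the
coefficient of a linear model of the measure on group membership,
which for a binary indicator is exactly the difference of group means;
the reference group (non-hygienic middle-aged workers, age 16 by
default and configurable) is coded 1, so positive coefficients mean
the reference group has the larger mean.  Restricted shuffles permute
labels only within the union of the two focal groups, conserving group
sizes; the assortativity tests shuffle the attribute across all
attribute-bearing nodes.

p-values are empirical and two-tailed with 1000 permutations by
default: a result is significant when fewer than 2.5% of permuted
values fall at or beyond the observed value in either tail, and the
reported p is the smaller tail (not doubled), matching that decision
rule.  Tail proportions use the add-one estimator — the observed
network counts as one permutation — so p = 0 cannot occur and the
minimum attainable p is `1/(n_perm+1)`; the plain-proportion variant
is available (`include_observed=False`) since published analyses
rarely state their tie handling.  Each test consumes one seeded
generator and records its seed, making every result bit-reproducible.
No multiple-testing correction is applied across the measure family,
mirroring the original analysis style; the run manifest notes this.

## Temporal spread

Spread assumes perfect transmission: at each event, an infected
participant infects the other, and infection acquired at one event is
transmissible at any strictly later event (simultaneous events resolve
in stored order within a single chronological pass).  Duration plays
no role under perfect transmission.  Whether infection should follow
nectar flow only is genuinely unclear — viruses ride donated food, but
uptake while receiving is also documented — so both semantics are
implemented: `forward` (donor infects receiver) and `both` (either
participant infects the other), with `both` the default and the mode
recorded in every report.  `both` reach is always a superset of
`forward` reach; at the default synthetic density the best-connected
seed reaches roughly 4–5% of the network in forward mode and 8–17% in
both mode, so mode choice materially changes super-spreader magnitudes
and forward mode is the one that reproduces low single-percent maxima.

Spread potential is the reached count divided by the total number of
networked individuals (seed excluded from the numerator).  The group
test recomputes the full spread analysis on each of 1000 time-shuffled
networks (event times permuted among events; participants and
durations untouched).  Internally all seeds propagate simultaneously
as per-node bitmasks, making one pass over the event list per network.

## Synthetic colony generator

The generator emulates a one-hour observation of a two-frame hive
holding five weekly cohorts of 300 marked workers (ages 2, 9, 16, 23,
30 days) plus a queen:

* `participation_rate = 0.22` — each worker independently joins the
  observable pool; the queen always participates.  With 280 events this
  yields ~260–280 networked bees and density ~0.0035–0.004, the sparse
  regime of a one-hour trophallaxis watch.  Because events are sampled
  i.i.d., ~18% of the pool never appears, so the realized node count
  sits slightly below the pool size.
* `n_events = 280`, start times uniform on the 3600 s horizon.
* durations: log-normal, log-mean 1.8 and log-sd 1.2 (median ~6 s,
  matching per-bee time medians at roughly one exchange each; expected
  maximum over 280 draws ~170 s, matching observed one-hour maxima),
  truncated by resampling to [2, 212] s — so the 2 s filter is the
  identity on generated data.
* partner choice: receiver weight `exp(−|Δage|/τ)` with
  `age_kernel_scale` τ = 30 d by default, giving age assortativity
  ~0.2 (the 0.15–0.25 range typical of real colonies); τ = None removes
  the preference, and smaller τ strengthens it monotonically.  Pairs
  with unknown age difference (the queen) use baseline weight scaled by
  `queen_interaction_rate` (default 2).
* hygienic workers: 64 by default, target ages drawn from
  Normal(19, 8.5) and snapped to the nearest cohort with spare workers;
  task profiles uncap-only / remove-only / both with probabilities
  (0.72, 0.22, 0.06), matching observed task mixes; one or two acts
  each, uniform on [−4 h, horizon] so most acts predate filming and
  exercise the pre-filming branch of the coding rule.
* `effect_delta` multiplies hygienic donor-selection weight by
  `1 − delta`: 0 makes hygienic and same-aged non-hygienic workers
  exchangeable by construction (the calibration condition); 1 silences
  hygienic donation entirely.

What the generator does **not** emulate: burstiness or within-bout
correlation (events are i.i.d. given weights), repeat-partner
preference, spatial structure, task switching, or any difference
between uncappers and removers.  Consequently, passing calibration and
recovery tests shows the inference machinery behaves correctly under
exchangeability and planted effects — not that real colonies satisfy
those conditions.  One deliberate realism: hygienic workers concentrate
in middle cohorts while partner choice is age-assortative, so hygienic
status inherits a *weak positive* assortativity through age; on most
seeds the unrestricted test correctly reads it as non-significant, but
occasional synthetic colonies flag it, which is a property of the
planted confounding rather than a false positive of the test.

## Verification at a glance

The test suite checks, among others: round-tripping of all file
formats; the hygienic coding rule against exhaustive enumeration of
act/event orderings; betweenness against brute-force path counting on
200 random small digraphs; eigenvector scores against dense
eigendecomposition; nominal assortativity against the hand-tabulated
mixing-matrix formula and an independent library implementation;
single-pass temporal reach against exhaustive time-increasing path
reachability on 200 random temporal networks in both modes; restricted
shuffle uniformity by chi-square; null calibration of the restricted
test on time-as-donor (rejection rate within [0.03, 0.07] of the
nominal 5% over 500 synthetic colonies at 200 permutations); power
against a planted donation deficit (median p < 0.025 at delta = 0.8
over 100 colonies, monotone in delta over {0, 0.4, 0.8}); age
assortativity recovery across kernel scales (≈0 without a kernel,
monotone in 1/τ over {20, 8, 3} d, ≥90% significant at τ = 3); and
byte-identical reruns of the full simulate/analyze/spread pipeline at
fixed seeds.  Problem sizes in the statistical suites (replicate and
permutation counts above) were chosen as the smallest that make the
pass bands sharp.

## Known limitations

* The linear-model coefficient is the difference of group means on the
  raw scale; heavy-tailed duration measures make it dominated by a few
  long exchanges, which is faithful to the published analysis style
  but statistically blunt.
* Reported p-values are per-measure; the eight-measure family carries
  the usual multiplicity caveat.
* The temporal-spread null permutes times only; nulls that rewire
  partners (datastream or edge permutations) probe different, stronger
  hypotheses and are out of scope.
* Unknown-age bees are silently excluded from age-based measures
  (with a reported count) rather than imputed.
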