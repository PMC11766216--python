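# trophnet

Social-network analysis of trophallaxis (mouth-to-mouth food sharing) in
marked honey bee colonies, focused on one question: are workers that
recently performed **hygienic tasks** — uncapping brood cells and removing
dead pupae, a frontline defense against brood disease — any less embedded
in the colony's food-sharing network than ordinary middle-aged workers of
the same caste?  Because trophallaxis is itself a disease transmission
route, a hygienic worker that keeps exchanging food is a plausible source
of colony-wide infection.

The package is for behavioral ecologists and social-insect researchers
working with time-stamped interaction logs from observation hives.  It
provides:

* **Network construction** — read delimited event logs (donor, receiver,
  start time, duration) and rosters (age, role, hygienic acts); drop
  exchanges under 2 s (too brief for nectar transfer); code each bee as
  hygienic unless *all* of its interactions preceded its first hygienic
  act; build a directed graph weighted by exchange counts and summed
  durations, and a time-ordered event sequence for dynamic analyses.
* **Measures** — directed degree and strength split by role (receptions /
  donations, time as receiver / donor), unnormalized directed betweenness,
  eigenvector centrality on the symmetrized duration-weighted adjacency
  (power iteration, max-normalized), edge density `E / N(N−1)`, and
  assortativity: Newman's nominal coefficient
  `r = (Σᵢ eᵢᵢ − Σᵢ aᵢbᵢ) / (1 − Σᵢ aᵢbᵢ)` on the edge mixing matrix, and
  the numeric form as the Pearson correlation of edge-endpoint values.
* **Inference** — node-permutation tests: the statistic is the slope of a
  linear model of the measure on group membership (exactly the difference
  of group means, reference group coded 1), compared to a null built from
  1000 label shuffles restricted to the two focal groups (hygienic vs
  non-hygienic 16-day-old workers), or unrestricted over all nodes for
  assortativity.  A result is significant when fewer than 2.5% of permuted
  values lie at or beyond it in either tail (two-tailed, empirical).
* **Temporal spread** — perfect-transmission SI spread over the
  time-ordered network: infection passes at each event (donor→receiver,
  or both directions for mouth-to-mouth contact) and is transmissible at
  any strictly later event.  Per-seed spread potential is the fraction of
  networked bees reached; group differences are tested against a null
  that randomly permutes event times.
* **A synthetic colony generator** — five weekly age cohorts of 300
  marked workers plus a queen, age-assortative partner choice, log-normal
  exchange durations on [2, 212] s, middle-aged hygienic workers with
  pre-filming act times, and two planted-truth knobs (age-kernel scale,
  hygienic donation deficit) so every stage of the pipeline can be tested
  against known ground truth.

## Worked example

Simulate a colony, analyze it, and run the spread analysis:

```sh
trophnet simulate --seed 42 --out demo/sim
# simulated colony: 280 events, 274 nodes, 280 edges, density 0.003743

trophnet analyze --events demo/sim/events.csv --roster demo/sim/roster.csv \
    --acts demo/sim/acts.csv --seed 1 --out demo/analysis
# analyzed 280 filtered events; 274 nodes, 280 edges; 9 hygienic and
# 54 reference workers in network

trophnet spread --events demo/sim/events.csv --roster demo/sim/roster.csv \
    --acts demo/sim/acts.csv --seed 2 --out demo/spread
# spread (both): max reach 7.66% of 274 nodes; group test p = 0.3477
```

`demo/analysis/group_comparison.csv` then holds the eight-measure group
comparison (sums and medians per group, coefficient, permutation p):

```
measure           focal_sum  focal_median  reference_sum  coefficient  p_reported
exchanges_total      21.000         2.000         97.000       -0.296       0.286
receptions            9.000         1.000         55.000        0.037       0.551
donations            12.000         1.000         42.000       -0.333       0.210
time_total          354.893        24.827       1862.529       -4.944       0.346
time_as_receiver    121.404        11.565       1001.229        4.917       0.363
time_as_donor       233.489         3.817        861.300       -9.861       0.178
betweenness          78.000         0.000        216.000       -3.796       0.164
eigenvector           0.000         0.000          0.171        0.019       0.309
```

and `assortativity.csv` the unrestricted permutation tests:

```
attribute        observed  p_reported  significant
hygienic_status    -0.038       0.124        False
age                 0.295       0.001         True
```

Read: the nine hygienic workers in this synthetic network exchange food
at rates indistinguishable from same-aged non-hygienic workers (all eight
coefficients non-significant — the generator planted no donation
deficit), workers do not assort by hygienic status, and the network is
significantly age-assortative (r = 0.295), exactly the structure the
generator plants.  The coefficient column is reference-minus-focal mean,
so positive values mean non-hygienic workers have the larger mean.
A `manifest.json` in every output directory records seeds, flags and
input hashes; identical seeds reproduce every output byte for byte.

The same analyses run on real observation-hive data by pointing
`--events/--roster/--acts` at your own files (formats documented in
`trophnet.events`).

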