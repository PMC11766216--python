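"""Synthetic colony generator: rosters, hygienic acts and event logs.

Produces data with the statistical structure the analysis pipeline
assumes, at the scale of a one-hour observation of a two-frame
observation hive: five marked age cohorts (2, 9, 16, 23 and 30 days,
300 workers each) plus a queen, of which roughly a fifth take part in
the filmed food-sharing network; a few hundred exchanges with
log-normal durations of at least 2 s; positive age assortativity driven
by an exponential age-distance kernel on partner choice; and hygienic
workers concentrated among middle-aged cohorts, each with one or two
uncap/remove acts that may predate filming (negative timestamps, from
the manual watch of the freeze-killed brood).

Two knobs make ground truth plantable: ``age_kernel_scale`` (smaller
means stronger age-assortative mixing; ``None`` removes the preference)
and ``effect_delta`` (multiplicative reduction of the donor-selection
weight of hygienic individuals; 0 makes hygienic and same-aged
non-hygienic workers exchangeable by construction, which is what the
permutation-test calibration relies on).

Events are sampled i.i.d. given the pair weights — no burstiness or
within-bout correlation — which is adequate for calibration and
recovery testing but deliberately simpler than real interaction
sequences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .events import HygienicAct, IndividualRecord, TrophallaxisEvent

QUEEN_ID = "queen"

DEFAULT_COHORTS = {2: 300, 9: 300, 16: 300, 23: 300, 30: 300}


@dataclass(frozen=True)
class ColonyConfig:
    """Tunable parameters of the synthetic colony.

    Defaults emulate the one-hour observation of a five-cohort marked
    colony: ~330 participating individuals, 280 exchanges, durations
    with median ~6 s truncated to [2, 212] s, hygienic ages centred
    near 19 +/- 8.5 days, and an age kernel yielding mild positive age
    assortativity.
    """

    cohort_sizes: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS)
    )
    #: probability that a worker takes part in the filmed network
    participation_rate: float = 0.22
    n_events: int = 280
    horizon: float = 3600.0
    #: exponential scale (days) of the age-distance partner kernel;
    #: ``None`` disables age preference entirely.  30 d yields mild
    #: positive age assortativity (~0.2) over 7-day cohort spacing.
    age_kernel_scale: float | None = 30.0
    #: partner weight of the queen relative to a baseline worker
    queen_interaction_rate: float = 2.0
    duration_log_mean: float = 1.8
    duration_log_sd: float = 1.2
    duration_floor: float = 2.0
    duration_cap: float = 212.0
    hygienic_age_mean: float = 19.0
    hygienic_age_sd: float = 8.5
    n_hygienic: int = 64
    #: probabilities that a hygienic worker is an uncapper-only,
    #: remover-only, or performs both tasks (uncapping dominates)
    task_profile_probs: tuple[float, float, float] = (0.72, 0.22, 0.06)
    #: hours of manual observation before filming; acts may fall there
    pre_observation_window: float = 14400.0
    #: multiplicative reduction of hygienic donor-selection weight
    effect_delta: float = 0.0
    colony_id: str = "sim"

    def __post_init__(self):
        if self.participation_rate <= 0 or self.participation_rate > 1:
            raise ValueError("participation_rate must lie in (0, 1]")
        if self.duration_floor < 2:
            raise ValueError("duration_floor must be >= 2 s")
        if not (0.0 <= self.effect_delta <= 1.0):
            raise ValueError("effect_delta must lie in [0, 1]")
        if self.age_kernel_scale is not None and self.age_kernel_scale <= 0:
            raise ValueError("age_kernel_scale must be positive or None")
        if self.queen_interaction_rate < 0:
            raise ValueError("queen_interaction_rate must be >= 0")
        if self.n_events < 0 or self.n_hygienic < 0:
            raise ValueError("counts must be non-negative")
        if abs(sum(self.task_profile_probs) - 1.0) > 1e-9:
            raise ValueError("task_profile_probs must sum to 1")


def generate_roster(config: ColonyConfig, rng: np.random.Generator) -> list[IndividualRecord]:
    """Generate the worker cohorts, one queen, and hygienic-act schedules.

    Cohort counts are exact.  The ``n_hygienic`` hygienic workers get
    target ages drawn from the hygienic age law, snapped to the nearest
    available cohort age; each receives one or two acts with a task
    drawn from {uncap, remove} and a time uniform on
    ``[-pre_observation_window, horizon]``.
    """
    ages = sorted(config.cohort_sizes)
    n_workers = sum(config.cohort_sizes.values())
    if config.n_hygienic > n_workers:
        raise ValueError(
            f"n_hygienic={config.n_hygienic} exceeds worker count {n_workers}"
        )

    workers: list[IndividualRecord] = []
    by_cohort: dict[int, list[int]] = {a: [] for a in ages}
    idx = 0
    for age in ages:
        for _ in range(config.cohort_sizes[age]):
            workers.append(
                IndividualRecord(
                    id=f"w{idx:04d}", age_days=age, role="worker",
                    colony_id=config.colony_id,
                )
            )
            by_cohort[age].append(idx)
            idx += 1

    # hygienic assignment: sample target ages, snap to nearest cohort
    # with spare (not yet hygienic) workers
    available = {a: list(by_cohort[a]) for a in ages}
    for a in ages:
        rng.shuffle(available[a])
    targets = rng.normal(config.hygienic_age_mean, config.hygienic_age_sd,
                         size=config.n_hygienic)
    age_arr = np.asarray(ages, dtype=float)
    for t in targets:
        order = np.argsort(np.abs(age_arr - t), kind="stable")
        for j in order:
            cohort = ages[j]
            if available[cohort]:
                widx = available[cohort].pop()
                break
        else:  # pragma: no cover - only if n_hygienic == n_workers
            raise ValueError("no workers left for hygienic assignment")
        profile = int(rng.choice(3, p=config.task_profile_probs))
        if profile == 2:  # performs both subtasks, one act each
            task_seq = ["uncap", "remove"]
        else:
            task = "uncap" if profile == 0 else "remove"
            task_seq = [task] * int(rng.integers(1, 3))
        acts = tuple(
            HygienicAct(
                task=t,
                act_time=float(
                    rng.uniform(-config.pre_observation_window, config.horizon)
                ),
            )
            for t in task_seq
        )
        workers[widx] = workers[widx].with_acts(acts)

    queen = IndividualRecord(
        id=QUEEN_ID, age_days=None, role="queen", colony_id=config.colony_id
    )
    return workers + [queen]


def _truncated_lognormal(config: ColonyConfig, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    a = (np.log(config.duration_floor) - config.duration_log_mean) / config.duration_log_sd
    b = (np.log(config.duration_cap) - config.duration_log_mean) / config.duration_log_sd
    z = stats.truncnorm.rvs(a, b, size=size, random_state=rng)
    return np.exp(config.duration_log_mean + config.duration_log_sd * z)


def generate_event_log(
    roster: Sequence[IndividualRecord],
    config: ColonyConfig,
    rng: np.random.Generator,
) -> list[TrophallaxisEvent]:
    """Sample ``n_events`` trophallaxis events over the participating pool.

    Workers join the pool independently with ``participation_rate``; the
    queen always participates (she is on the filmed brood frame).  The
    donor is drawn with weight 1 for workers — times ``1 - effect_delta``
    for hygienic workers — and ``queen_interaction_rate`` for the queen.
    Given the donor, the receiver is drawn with weight
    ``exp(-|age_d - age_r| / age_kernel_scale)``; pairs with an unknown
    age difference (any pair involving the queen) use the baseline
    weight, scaled by ``queen_interaction_rate`` when the receiver is
    the queen.  Start times are uniform on ``[0, horizon)``; durations
    follow the truncated log-normal law.
    """
    workers = [r for r in roster if r.role == "worker"]
    queen = next((r for r in roster if r.role == "queen"), None)

    participating = [w for w in workers
                     if rng.random() < config.participation_rate]
    pool: list[IndividualRecord] = list(participating)
    if queen is not None:
        pool.append(queen)
    if len(pool) < 2 or config.n_events == 0:
        return []

    tau = config.age_kernel_scale
    hygienic_ids = {r.id for r in roster if r.hygienic_acts}

    # donor weights
    donor_w = np.empty(len(pool))
    for i, r in enumerate(pool):
        if r.role == "queen":
            donor_w[i] = config.queen_interaction_rate
        elif r.id in hygienic_ids:
            donor_w[i] = 1.0 - config.effect_delta
        else:
            donor_w[i] = 1.0
    total_w = donor_w.sum()
    if total_w == 0:
        raise ValueError("all donor weights are zero")
    donor_p = donor_w / total_w

    # receiver weights depend only on the donor's cohort age (or queen)
    cohort_ages = sorted({r.age_days for r in participating})
    members: dict[object, np.ndarray] = {
        a: np.array([i for i, r in enumerate(pool) if r.age_days == a])
        for a in cohort_ages
    }
    queen_index = len(pool) - 1 if queen is not None else None

    def receiver_categories(donor_age):
        """(category list, probability list); categories are cohort ages or 'queen'."""
        cats, weights = [], []
        for a in cohort_ages:
            if donor_age is None or tau is None:
                w = 1.0
            else:
                w = float(np.exp(-abs(donor_age - a) / tau))
            cats.append(a)
            weights.append(w * len(members[a]))
        if queen_index is not None and donor_age is not None:
            cats.append("queen")
            weights.append(config.queen_interaction_rate)
        w = np.asarray(weights)
        return cats, w / w.sum()

    cat_cache = {}
    for a in cohort_ages + [None]:
        cat_cache[a] = receiver_categories(a)

    donors = rng.choice(len(pool), size=config.n_events, p=donor_p)
    start_times = rng.uniform(0.0, config.horizon, size=config.n_events)
    durations = _truncated_lognormal(config, config.n_events, rng)

    events: list[TrophallaxisEvent] = []
    for k in range(config.n_events):
        di = int(donors[k])
        donor = pool[di]
        cats, probs = cat_cache[donor.age_days]
        while True:
            c = cats[int(rng.choice(len(cats), p=probs))]
            if c == "queen":
                ri = queen_index
            else:
                ri = int(rng.choice(members[c]))
            if ri != di:
                break
        events.append(
            TrophallaxisEvent(
                donor_id=donor.id,
                receiver_id=pool[ri].id,
                start_time=float(start_times[k]),
                duration=float(durations[k]),
                colony_id=config.colony_id,
            )
        )
    return events


def planted_truth(roster: Sequence[IndividualRecord], config: ColonyConfig) -> dict:
    """Machine-readable record of the generator's knobs and ground truth."""
    truth = asdict(config)
    truth["cohort_sizes"] = {str(k): v for k, v in config.cohort_sizes.items()}
    truth["task_profile_probs"] = list(config.task_profile_probs)
    truth["hygienic_ids"] = sorted(r.id for r in roster if r.hygienic_acts)
    truth["queen_id"] = next(
        (r.id for r in roster if r.role == "queen"), None
    )
    return truth


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def generate_colony(
    config: ColonyConfig, rng: np.random.Generator
) -> tuple[list[IndividualRecord], list[TrophallaxisEvent], dict]:
    """Convenience: roster, event log and planted-truth record in one call."""
    roster = generate_roster(config, rng)
    events = generate_event_log(roster, config, rng)
    return roster, events, planted_truth(roster, config)
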