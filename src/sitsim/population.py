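"""Agent population state, initialization, and the daily step.

The population is stored as a structure of arrays (one numpy array per state
variable over all living individuals) rather than one object per insect; this
keeps daily steps vectorized and fast at the tens of thousands of agents the
uncontrolled scenarios reach.  ``Insect`` offers a per-agent record view for
inspection and testing.

Each simulated day runs eight processes in fixed order:

1. development (immature -> mature once age exceeds the immature duration);
2. [boosted] disease progression;
3. [SIT/boosted] the single sterile-male release, on the release day only,
   after development and before reproduction;
4. [boosted] lek transmission between mature males;
5. mating and offspring production;
6. vertical transmission (inside offspring production);
7. horizontal transmission across today's mating pairs;
8. senescence; then ages and the day counter advance by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biocide, reproduction
from .params import SCENARIOS, SimParams
from .reproduction import FEMALE, MALE

__all__ = [
    "RELEASED_GEN",
    "Insect",
    "Population",
    "DailyRecord",
    "StepCounts",
    "init_population",
    "step",
    "record",
]

#: Generation tag of released sterile males (outside the wild lineage count).
RELEASED_GEN = -1

_FIELDS = (
    "sex", "age", "generation", "contaminated", "tsick", "sterile",
    "comp", "matings_done", "first_fertile", "last_fertile", "n_fertile", "alive",
)


@dataclass(frozen=True)
class Insect:
    """Read-only per-agent view of one individual."""

    sex: str
    stage: str
    age: int
    generation: int
    health: str
    tsick: int
    reproductive_status: str
    competitiveness: float
    matings_done: int
    n_fertile_matings: int


class Population:
    """All living individuals of one replicate, as parallel arrays.

    Attributes
    ----------
    day : current day counter (starts at 0).
    released : whether the single sterile-male release already happened.
    rng : the replicate's random generator; every stochastic draw of the
        simulation consumes this one stream in scheduled order.
    sex, age, generation, contaminated, tsick, sterile, comp,
    matings_done, first_fertile, last_fertile, n_fertile, alive :
        per-agent arrays; the mating-history fields (first/last partner
        status, fertile-partner count, matings done) are meaningful for
        females and are a sufficient statistic of the 0/1 partner history
        for every sperm-competition regime.
    """

    __slots__ = ("day", "released", "rng", "cwild", "timmature") + _FIELDS

    def __init__(self, rng: np.random.Generator, cwild: float, timmature: int):
        self.day = 0
        self.released = False
        self.rng = rng
        self.cwild = float(cwild)
        self.timmature = int(timmature)
        self.sex = np.empty(0, dtype=np.uint8)
        self.age = np.empty(0, dtype=np.int32)
        self.generation = np.empty(0, dtype=np.int32)
        self.contaminated = np.empty(0, dtype=bool)
        self.tsick = np.empty(0, dtype=np.int32)
        self.sterile = np.empty(0, dtype=bool)
        self.comp = np.empty(0, dtype=np.float64)
        self.matings_done = np.empty(0, dtype=np.int16)
        self.first_fertile = np.empty(0, dtype=np.int8)
        self.last_fertile = np.empty(0, dtype=np.int8)
        self.n_fertile = np.empty(0, dtype=np.int16)
        self.alive = np.empty(0, dtype=bool)

    @property
    def size(self) -> int:
        return int(self.alive.sum()) if self.age.size else 0

    def append(self, *, sex, age, generation, contaminated, sterile, comp,
               tsick=None) -> None:
        """Add a batch of agents (newborns or released males)."""
        n = len(sex)
        if n == 0:
            return
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.uint8)])
        self.age = np.concatenate([self.age, np.asarray(age, np.int32)])
        self.generation = np.concatenate(
            [self.generation, np.asarray(generation, np.int32)])
        self.contaminated = np.concatenate(
            [self.contaminated, np.asarray(contaminated, bool)])
        if tsick is None:
            tsick = np.zeros(n, dtype=np.int32)
        self.tsick = np.concatenate([self.tsick, np.asarray(tsick, np.int32)])
        self.sterile = np.concatenate([self.sterile, np.asarray(sterile, bool)])
        self.comp = np.concatenate([self.comp, np.asarray(comp, np.float64)])
        self.matings_done = np.concatenate(
            [self.matings_done, np.zeros(n, np.int16)])
        self.first_fertile = np.concatenate(
            [self.first_fertile, np.full(n, -1, np.int8)])
        self.last_fertile = np.concatenate(
            [self.last_fertile, np.full(n, -1, np.int8)])
        self.n_fertile = np.concatenate([self.n_fertile, np.zeros(n, np.int16)])
        self.alive = np.concatenate([self.alive, np.ones(n, bool)])

    def compact(self) -> None:
        """Drop dead agents from the arrays."""
        if self.alive.all():
            return
        keep = self.alive
        for name in _FIELDS:
            setattr(self, name, getattr(self, name)[keep])

    def insect(self, i: int) -> Insect:
        """Per-agent record view (testing/inspection convenience)."""
        return Insect(
            sex="male" if self.sex[i] == MALE else "female",
            stage="mature" if self.age[i] > self.timmature else "immature",
            age=int(self.age[i]),
            generation=int(self.generation[i]),
            health="contaminated" if self.contaminated[i] else "healthy",
            tsick=int(self.tsick[i]),
            reproductive_status="sterile" if self.sterile[i] else "fertile",
            competitiveness=float(self.comp[i]),
            matings_done=int(self.matings_done[i]),
            n_fertile_matings=int(self.n_fertile[i]),
        )

    def insects(self) -> list[Insect]:
        return [self.insect(i) for i in range(self.age.size) if self.alive[i]]


@dataclass(frozen=True)
class DailyRecord:
    """End-of-day observation of one replicate."""

    day: int
    N_total: int
    pN: float
    n_sterile: int
    n_contaminated: int
    counts_by_generation: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StepCounts:
    """Bookkeeping of one daily step: N(d+1) = N(d) + births + releases - deaths."""

    births: int
    releases: int
    deaths: int


def init_population(params: SimParams, seed: int) -> Population:
    """Found a replicate population of N0 healthy, fertile individuals.

    Sexes alternate deterministically (exactly N0/2 of each); ages are drawn
    uniformly on [0, Tgeneration) whole days to represent overlapping
    generations, so some founders start mature.  Founder females have empty
    mating histories; a founder initialized past several mating-age
    thresholds catches her schedule up at one mating per day.
    """
    rng = np.random.default_rng(seed)
    pop = Population(rng, params.Cwild, params.Timmature)
    n = params.N0
    sex = np.tile([MALE, FEMALE], n // 2).astype(np.uint8)
    age = rng.integers(0, params.Tgeneration, size=n).astype(np.int32)
    pop.append(
        sex=sex,
        age=age,
        generation=np.zeros(n, np.int32),
        contaminated=np.zeros(n, bool),
        sterile=np.zeros(n, bool),
        comp=np.full(n, params.Cwild),
    )
    return pop


def _release(pop: Population, params: SimParams, ratio: int,
             inoculated: bool) -> int:
    """Add ratio x (wild mature males) sterile males, freshly mature."""
    wild = pop.alive & (pop.sex == MALE) & ~pop.sterile \
        & (pop.age > params.Timmature)
    n_new = int(ratio) * int(wild.sum())
    if n_new:
        pop.append(
            sex=np.full(n_new, MALE, np.uint8),
            age=np.full(n_new, params.Timmature + 1, np.int32),
            generation=np.full(n_new, RELEASED_GEN, np.int32),
            contaminated=np.full(n_new, inoculated, bool),
            sterile=np.ones(n_new, bool),
            comp=np.full(n_new, params.Csterile),
        )
    pop.released = True
    return n_new


def step(pop: Population, params: SimParams, scenario: str,
         release_day: int | None = None, ratio: int | None = None) -> StepCounts:
    """Advance the population one day through the eight scheduled processes.

    ``scenario`` is one of ``control``, ``sit``, ``boosted``; the biocide
    processes run only under ``boosted`` and the release only under
    ``sit``/``boosted`` on ``release_day`` (once per simulation).  Returns
    the day's birth/release/death counts.
    """
    scenario = scenario.lower()
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    boosted = scenario == "boosted"
    if ratio is None:
        ratio = params.ratio

    # 1. development is implicit: stage == mature <=> age > Timmature.
    deaths = 0
    # 2. disease progression
    if boosted:
        deaths += biocide.progress_disease(pop, params)
    # 3. single release of sterile males
    releases = 0
    if (scenario != "control" and release_day is not None
            and pop.day == release_day and not pop.released):
        releases = _release(pop, params, ratio, inoculated=boosted)
    # 4. lek transmission
    if boosted:
        biocide.lek_transmission(pop, params.Pc, params.Timmature)
    # 5 & 6. mating, laying, vertical transmission
    births, pairs = reproduction.mate_and_lay(pop, params, vertical=boosted)
    # 7. horizontal transmission across today's pairs
    if boosted and pairs is not None:
        biocide.mating_transmission(pop, pairs[0], pairs[1], params.Ph)
    # 8. senescence, then ages and the day advance
    pop.age += 1
    senescent = pop.alive & (pop.age > params.Tgeneration)
    deaths += int(senescent.sum())
    pop.alive[senescent] = False
    pop.compact()
    pop.day += 1
    return StepCounts(births=births, releases=releases, deaths=deaths)


def record(pop: Population, params: SimParams) -> DailyRecord:
    """End-of-day observation: size, fraction of NX, sterile and
    contaminated counts, and the generation composition."""
    n = pop.size
    gens, counts = (np.unique(pop.generation[pop.alive], return_counts=True)
                    if n else (np.empty(0, int), np.empty(0, int)))
    return DailyRecord(
        day=pop.day,
        N_total=n,
        pN=n / params.NX,
        n_sterile=int(pop.sterile[pop.alive].sum()) if n else 0,
        n_contaminated=int(pop.contaminated[pop.alive].sum()) if n else 0,
        counts_by_generation={int(g): int(c) for g, c in zip(gens, counts)},
    )
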