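"""Seed-matched control / SIT / boosted-SIT scenario runs.

The experimental unit is one replicate seed.  A control run (no
intervention) determines two days: ``t_plus_1``, when the uncontrolled
population first reaches the problematic size NX = nx_multiplier * N0, and
``t``, when adults of the generation preceding the problematic one start to
appear — the release day.  SIT and boosted runs then re-simulate from the
identical seed (so trajectories match day-for-day until the release) with a
single sterile-male release at day ``t``, and are scored by the population
size at day ``t_plus_1``.  Sweeping the release ratio upward gives the first
successful ratio per scenario, and the gain G compares the two scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SimParams
from .population import DailyRecord, init_population, record, step

__all__ = [
    "FAIL",
    "ControlTiming",
    "ScenarioResult",
    "ControlDidNotReachNX",
    "expected_generations",
    "run_control",
    "release_sterile_males",
    "run_treatment",
    "ratio_sweep",
    "gain",
    "run_scenario_set",
]

#: Sweep outcome marker: no ratio up to max_ratio achieved suppression.
FAIL = None


class ControlDidNotReachNX(RuntimeError):
    """The uncontrolled population never reached NX within the day cap."""


def expected_generations(f: float) -> int:
    """Expected wild generations for a population to grow 1000-fold.

    Each female contributes ``f`` recruits, half of them daughters, so the
    per-generation multiplication factor is f/2 and the generation count is
    ``ceil(ln 1000 / (ln f - ln 2))``.  Requires f > 2 (a growing population).
    """
    if f <= 2:
        raise ValueError(f"F must exceed 2 for a growing population, got {f}")
    return math.ceil(math.log(1000.0) / (math.log(f) - math.log(2.0)))


@dataclass(frozen=True)
class ControlTiming:
    """Release timing derived from one uncontrolled run."""

    t: int
    t_plus_1: int
    nb_generation: int
    t_fallback: bool = False  # True when t came from the fallback rule


@dataclass
class ScenarioResult:
    """Per-replicate outcome of the full control/SIT/boosted protocol."""

    seed: int
    timing: ControlTiming
    n_control_t1: int
    ratio_sit: int | None
    ratio_boosted: int | None
    n_t1_sit: dict = field(default_factory=dict)
    n_t1_boosted: dict = field(default_factory=dict)

    @property
    def sit_failed(self) -> bool:
        return self.ratio_sit is FAIL

    @property
    def boosted_failed(self) -> bool:
        return self.ratio_boosted is FAIL

    @property
    def boosted_rescued(self) -> bool:
        return self.sit_failed and not self.boosted_failed

    @property
    def G(self) -> float | None:
        return gain(self.ratio_sit, self.ratio_boosted)


def run_control(params: SimParams, seed: int, collect: bool = True,
                ) -> tuple[ControlTiming, list[DailyRecord]]:
    """Simulate without intervention until the population reaches NX.

    Returns the timing (t, t+1) and, when ``collect``, the daily records.
    ``t`` is the first day on which any individual of generation
    nb_generation - 1 is mature; if that generation never matures before
    ``t_plus_1`` (or would mature at day 0), ``t`` falls back to the first
    maturation day of the latest generation seen before ``t_plus_1``.
    Raises :class:`ControlDidNotReachNX` after 50 x Tgeneration days.
    """
    nbg = expected_generations(params.F)
    pop = init_population(params, seed)
    records: list[DailyRecord] = []
    first_mature_day: dict[int, int] = {}
    cap = 50 * params.Tgeneration
    t_plus_1 = None
    while True:
        # Maturity after today's development == age > Timmature at day start.
        mature_gens = np.unique(
            pop.generation[pop.alive & (pop.age > params.Timmature)])
        for g in mature_gens:
            first_mature_day.setdefault(int(g), pop.day)
        step(pop, params, "control")
        if collect:
            records.append(record(pop, params))
        if pop.size >= params.NX:
            t_plus_1 = pop.day
            break
        if pop.day >= cap:
            raise ControlDidNotReachNX(
                f"population never reached NX={params.NX} within {cap} days "
                f"(seed {seed})")
    target = nbg - 1
    t = first_mature_day.get(target)
    fallback = False
    if t is None or t < 1 or t >= t_plus_1:
        fallback = True
        usable = {g: d for g, d in first_mature_day.items()
                  if 1 <= d < t_plus_1}
        if not usable:
            raise ControlDidNotReachNX(
                f"no maturation day available for release timing (seed {seed})")
        t = usable[max(usable)]
    return ControlTiming(t=int(t), t_plus_1=int(t_plus_1),
                         nb_generation=nbg, t_fallback=fallback), records


def release_sterile_males(pop, params: SimParams, ratio: int,
                          inoculated: bool) -> int:
    """Perform the single sterile-male release on an external population.

    Adds ratio x (wild mature males) sterile, freshly mature males of
    competitiveness Csterile, contaminated when ``inoculated``.  Rejects a
    second release.
    """
    from .population import _release

    if pop.released:
        raise RuntimeError("the release is performed only once per simulation")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    return _release(pop, params, ratio, inoculated)


def run_treatment(params: SimParams, seed: int, scenario: str, ratio: int,
                  timing: ControlTiming, collect: bool = False,
                  ) -> tuple[int, list[DailyRecord]]:
    """Re-simulate from the same seed with a release at day t.

    Returns the population size at day ``t_plus_1`` (every living
    individual: released sterile males still alive at that day are part of
    the count, exactly as the daily size observation sees them) and the
    daily records when ``collect``.  Because the same seed replays the same
    draws, the trajectory is identical to the control run until the release
    day.
    """
    pop = init_population(params, seed)
    records: list[DailyRecord] = []
    while pop.day < timing.t_plus_1:
        step(pop, params, scenario, release_day=timing.t, ratio=ratio)
        if collect:
            records.append(record(pop, params))
    return pop.size, records


def ratio_sweep(params: SimParams, seed: int, scenario: str,
                timing: ControlTiming) -> tuple[int | None, dict[int, int]]:
    """First release ratio in 1..max_ratio that suppresses the population.

    Success means N(t+1) < success_fraction * NX; the sweep stops at the
    first success and returns ``(ratio, {ratio: N(t+1)})``, or ``(FAIL, ...)``
    if no ratio up to the cap succeeds.
    """
    threshold = params.success_fraction * params.NX
    n_by_ratio: dict[int, int] = {}
    for ratio in range(1, params.max_ratio + 1):
        n, _ = run_treatment(params, seed, scenario, ratio, timing)
        n_by_ratio[ratio] = n
        if n < threshold:
            return ratio, n_by_ratio
    return FAIL, n_by_ratio


def gain(ratio_sit: int | None, ratio_boosted: int | None) -> float | None:
    """Gain of boosted SIT over SIT in released males.

    G = (ratio_SIT - ratio_SIT_b) / (ratio_SIT + ratio_SIT_b) when both
    succeed; G = 1 when SIT fails but boosted SIT succeeds (the boosted
    technique contributes where SIT cannot); undefined (None) when both
    fail.  Positive G means boosted SIT needs fewer released males.
    """
    if ratio_sit is FAIL and ratio_boosted is FAIL:
        return None
    if ratio_sit is FAIL:
        return 1.0
    if ratio_boosted is FAIL:
        return -1.0
    return (ratio_sit - ratio_boosted) / (ratio_sit + ratio_boosted)


def run_scenario_set(params: SimParams, seed: int,
                     control_cache: dict | None = None,
                     sit_cache: dict | None = None) -> ScenarioResult:
    """Full protocol for one replicate: control, SIT sweep, boosted sweep.

    Optional caches (keyed by seed) let a caller reuse control timings and
    SIT sweeps across biocide parameter combinations, which cannot affect
    them.
    """
    if control_cache is not None and seed in control_cache:
        timing, n_control = control_cache[seed]
    else:
        timing, recs = run_control(params, seed, collect=True)
        n_control = recs[-1].N_total
        if control_cache is not None:
            control_cache[seed] = (timing, n_control)
    if sit_cache is not None and seed in sit_cache:
        ratio_sit, n_sit = sit_cache[seed]
    else:
        ratio_sit, n_sit = ratio_sweep(params, seed, "sit", timing)
        if sit_cache is not None:
            sit_cache[seed] = (ratio_sit, n_sit)
    ratio_boosted, n_boosted = ratio_sweep(params, seed, "boosted", timing)
    return ScenarioResult(
        seed=seed, timing=timing, n_control_t1=n_control,
        ratio_sit=ratio_sit, ratio_boosted=ratio_boosted,
        n_t1_sit=n_sit, n_t1_boosted=n_boosted,
    )
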