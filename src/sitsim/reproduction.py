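"""Female mating schedule, competitiveness-weighted partner choice, sperm
competition, and offspring creation.

Females mate a fixed number of times (``Nmating``) over their adult life, at
ages spread evenly across the adult span.  Partner choice is weighted by male
competitiveness.  The number of fertilized eggs per laying event depends on
the sperm-competition regime and the female's mating history, a sequence of
0 (sterile partner) / 1 (fertile partner) flags.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

from .params import SimParams

__all__ = [
    "mating_schedule",
    "choose_mate",
    "neggs",
    "expected_neggs",
    "stochastic_round",
    "produce_offspring",
    "mate_and_lay",
]

MALE = 0
FEMALE = 1


@lru_cache(maxsize=None)
def mating_schedule(timmature: int, tgeneration: int, nmating: int) -> tuple[int, ...]:
    """Ages (days) at which a female becomes eligible for her k-th mating.

    The adult span is divided into ``nmating`` equal windows; a female
    attempts her k-th mating on the first day her age strictly exceeds
    threshold k (and a mature male exists), having completed k-1 matings.

    Returns a strictly increasing tuple of ``nmating`` whole-day thresholds,
    the first being the maturation age ``timmature``.
    """
    if nmating < 1:
        raise ValueError("nmating must be >= 1")
    span = tgeneration - timmature
    if span <= 0:
        raise ValueError("tgeneration must exceed timmature")
    if nmating > span:
        raise ValueError(
            f"nmating={nmating} does not fit in an adult span of {span} days"
        )
    return tuple(timmature + (k * span) // nmating for k in range(nmating))


def choose_mate(weights: Sequence[float], rng: np.random.Generator) -> int:
    """Pick one male index with probability proportional to its weight.

    Implemented through a cumulative-probability vector: a uniform draw on
    [0, sum(weights)) selects the male whose cumulative interval contains it.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("no males to choose from")
    if np.any(w <= 0):
        raise ValueError("competitiveness weights must be positive")
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def _choose_mates(comp: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized ``choose_mate``: n independent weighted draws."""
    cum = np.cumsum(comp)
    draws = rng.random(n) * cum[-1]
    return np.searchsorted(cum, draws, side="right")


def expected_neggs(
    f: float, nmating: int, regime: str, history: Sequence[int]
) -> float:
    """Expected fertilized eggs for one laying event, before rounding.

    first : F/Nmating if the female's first partner was fertile, else 0.
    last  : F/Nmating if the partner of the current event was fertile, else 0.
    share : mean(history) * F/Nmating — paternity shared over all partners
            to date, so only the fertile fraction of the clutch is viable.
    """
    if not history:
        raise ValueError("a laying event requires at least one mating")
    base = f / nmating
    if regime == "first":
        return base * history[0]
    if regime == "last":
        return base * history[-1]
    if regime == "share":
        return base * (sum(history) / len(history))
    raise ValueError(f"unknown sperm-competition regime {regime!r}")


def stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round each value to floor(x) plus a Bernoulli(frac(x)) extra unit.

    Preserves the expectation, so fractional egg counts (share regime, or F
    not divisible by Nmating) do not bias the population growth rate.
    Consumes no randomness when every value is already integral.
    """
    x = np.asarray(x, dtype=float)
    k = np.floor(x)
    frac = x - k
    if np.any(frac > 0):
        k = k + (rng.random(x.shape) < frac)
    return k.astype(np.int64)


def neggs(
    f: float,
    nmating: int,
    regime: str,
    history: Sequence[int],
    rng: np.random.Generator | None = None,
) -> int:
    """Realized fertilized-egg count for one laying event.

    Non-integer expectations are realized by stochastic rounding; pass a
    generator for reproducibility (one is created ad hoc otherwise).
    """
    expected = expected_neggs(f, nmating, regime, history)
    if rng is None:
        rng = np.random.default_rng()
    return int(stochastic_round(np.array([expected]), rng)[0])


def produce_offspring(pop, mother_idx: np.ndarray, eggs: np.ndarray,
                      pv: float, vertical: bool) -> int:
    """Append the offspring of this day's laying events to the population.

    Each egg becomes an immature, age-0, fertile individual of the mother's
    generation + 1; sex is drawn evenly at random.  If vertical transmission
    is active, each offspring of a contaminated mother is independently
    contaminated with probability ``pv`` (its disease clock stays frozen at 0
    until maturity).
    """
    total = int(eggs.sum())
    if total == 0:
        return 0
    rng = pop.rng
    moms = np.repeat(mother_idx, eggs)
    sex = np.where(rng.random(total) < 0.5, FEMALE, MALE).astype(np.uint8)
    contaminated = np.zeros(total, dtype=bool)
    if vertical and pv > 0:
        mom_cont = pop.contaminated[moms]
        n_exposed = int(mom_cont.sum())
        if n_exposed:
            contaminated[mom_cont] = rng.random(n_exposed) < pv
    pop.append(
        sex=sex,
        age=np.zeros(total, dtype=np.int32),
        generation=pop.generation[moms] + 1,
        contaminated=contaminated,
        sterile=np.zeros(total, dtype=bool),
        comp=np.full(total, pop.cwild),
    )
    return total


def mate_and_lay(pop, params: SimParams, vertical: bool):
    """One day of mating and egg laying.

    Every eligible female (mature, within an unused mating window, below her
    lifetime mating count) chooses one mature male, weighted by
    competitiveness; males serve any number of females per day.  The mating
    is recorded in her history (1 = fertile partner, 0 = sterile), the
    fertilized-egg count follows the sperm-competition regime, and offspring
    are created immediately.  With no mature male, attempts are deferred (no
    history change, no randomness consumed).

    Returns ``(n_births, pairs)`` where ``pairs`` is an ``(females, males)``
    index tuple of today's matings (used afterwards for horizontal
    transmission), or ``None`` if no mating occurred.
    """
    thr = np.asarray(
        mating_schedule(params.Timmature, params.Tgeneration, params.Nmating)
    )
    mature = pop.alive & (pop.age > params.Timmature)
    male_idx = np.flatnonzero(mature & (pop.sex == MALE))
    if male_idx.size == 0:
        return 0, None
    fem = mature & (pop.sex == FEMALE) & (pop.matings_done < params.Nmating)
    fem_idx = np.flatnonzero(fem)
    if fem_idx.size == 0:
        return 0, None
    # A female attempts her k-th mating (at most one per day) once her age
    # exceeds threshold k; a delayed opportunity is retried daily, so
    # founders initialized past several thresholds catch their schedule up.
    eligible = pop.age[fem_idx] > thr[pop.matings_done[fem_idx]]
    fem_idx = fem_idx[eligible]
    if fem_idx.size == 0:
        return 0, None

    mates = male_idx[_choose_mates(pop.comp[male_idx], fem_idx.size, pop.rng)]
    fertile = (~pop.sterile[mates]).astype(np.int8)

    first = pop.first_fertile[fem_idx]
    first = np.where(first < 0, fertile, first)
    pop.first_fertile[fem_idx] = first
    pop.last_fertile[fem_idx] = fertile
    pop.n_fertile[fem_idx] += fertile
    pop.matings_done[fem_idx] += 1

    base = params.F / params.Nmating
    if params.Csperm == "first":
        expected = base * first
    elif params.Csperm == "last":
        expected = base * fertile
    else:  # share: fertile fraction of all partners to date
        expected = base * pop.n_fertile[fem_idx] / pop.matings_done[fem_idx]
    eggs = stochastic_round(expected, pop.rng)
    births = produce_offspring(pop, fem_idx, eggs, params.Pv, vertical)
    return births, (fem_idx, mates)
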