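"""Biocide transmission routes and disease progression.

The biocide spreads along three routes: horizontally during mating (Ph),
vertically from contaminated mothers to offspring (Pv, applied inside
offspring creation), and between mature males aggregating in leks (Pc).
A contaminated adult runs a disease clock; when it reaches the lethal
window the individual dies with probability ``Virulence``, otherwise it
heals with no acquired immunity and can be contaminated again.

The lethal time is defined as a fraction of the mature phase, so disease
clocks of contaminated immatures (vertical route) stay frozen at zero
until maturation.
"""

from __future__ import annotations

import numpy as np

from .params import SimParams
from .reproduction import MALE

__all__ = ["progress_disease", "lek_transmission", "mating_transmission"]


def progress_disease(pop, params: SimParams) -> int:
    """Advance disease clocks one day; kill or heal at the window end.

    Only mature contaminated individuals age their clock.  When the clock
    reaches ``Tcontamination`` days the individual dies with probability
    ``Virulence`` and otherwise returns to the healthy state with a reset
    clock.  Returns the number of biocide deaths.
    """
    sick = pop.alive & pop.contaminated & (pop.age > params.Timmature)
    if not sick.any():
        return 0
    pop.tsick[sick] += 1
    due = np.flatnonzero(sick & (pop.tsick >= params.Tcontamination))
    if due.size == 0:
        return 0
    v = params.Virulence
    if v >= 1.0:
        dies = np.ones(due.size, dtype=bool)
    elif v <= 0.0:
        dies = np.zeros(due.size, dtype=bool)
    else:
        dies = pop.rng.random(due.size) < v
    pop.alive[due[dies]] = False
    survivors = due[~dies]
    pop.contaminated[survivors] = False
    pop.tsick[survivors] = 0
    return int(dies.sum())


def lek_transmission(pop, pc: float, timmature: int) -> int:
    """Male-to-male transmission during lekking.

    If at least one contaminated mature male is present, every healthy
    mature male is independently contaminated with probability ``pc``
    (one pooled lek event per day).  Females and immatures are unaffected.
    Returns the number of new contaminations.
    """
    if pc <= 0.0:
        return 0
    lek = pop.alive & (pop.sex == MALE) & (pop.age > timmature)
    if not (lek & pop.contaminated).any():
        return 0
    healthy = np.flatnonzero(lek & ~pop.contaminated)
    if healthy.size == 0:
        return 0
    hit = healthy[pop.rng.random(healthy.size) < pc]
    pop.contaminated[hit] = True
    pop.tsick[hit] = 0
    return int(hit.size)


def mating_transmission(pop, fem_idx: np.ndarray, male_idx: np.ndarray,
                        ph: float) -> int:
    """Horizontal transmission across this day's mating pairs.

    For each pair with exactly one contaminated partner, the healthy one is
    contaminated with probability ``ph`` (either direction).  All statuses
    are read before any update, so transmission uses pre-mating health:
    offspring already laid today are unaffected, and chains of same-day
    second-hand transmission cannot occur.  Returns new contaminations.
    """
    if ph <= 0.0 or fem_idx is None:
        return 0
    status_f = pop.contaminated[fem_idx]
    status_m = pop.contaminated[male_idx]
    disc = status_f != status_m
    if not disc.any():
        return 0
    d_f = fem_idx[disc]
    d_m = male_idx[disc]
    hit = pop.rng.random(d_f.size) < ph
    # the healthy member of each transmitting pair becomes contaminated
    newly = np.where(pop.contaminated[d_m[hit]], d_f[hit], d_m[hit])
    pop.contaminated[newly] = True
    pop.tsick[newly] = 0
    return int(np.unique(newly).size)  # a male may be hit via several pairs
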