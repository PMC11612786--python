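"""Model parameters and derived constants.

All durations are whole days: the simulator advances in daily time steps, so
every derived duration (immature phase, lethal window, mating-age thresholds)
is rounded to an integer number of days.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = [
    "SPERM_REGIMES",
    "SCENARIOS",
    "SimParams",
    "derive_timmature",
    "lethal_window",
]

#: Sperm-competition regimes: which mating(s) in a female's history sire a clutch.
SPERM_REGIMES = ("first", "last", "share")

#: Simulation scenarios: no control, sterile-male release, and sterile males
#: additionally carrying a biocide.
SCENARIOS = ("control", "sit", "boosted")


def _round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (for positive x)."""
    return int(math.floor(x + 0.5))


def derive_timmature(tgeneration: int, pimmature: float) -> int:
    """Days spent in the immature stage.

    The immature duration is the fraction ``pimmature`` (a percentage) of the
    total lifespan ``tgeneration``, rounded to the nearest whole day.

    Parameters
    ----------
    tgeneration : int
        Individual lifespan in days (>= 2).
    pimmature : float
        Percentage of the lifespan spent immature, strictly between 0 and 100.
    """
    if tgeneration < 2:
        raise ValueError(f"tgeneration must be >= 2 days, got {tgeneration}")
    if not 0.0 < pimmature < 100.0:
        raise ValueError(f"pimmature must be in (0, 100), got {pimmature}")
    t_imm = _round_half_up(tgeneration * pimmature / 100.0)
    if not 0 < t_imm < tgeneration:
        raise ValueError(
            f"immature duration {t_imm} d must fall strictly inside "
            f"(0, {tgeneration}); adjust pimmature"
        )
    return t_imm


def lethal_window(lt: float, tgeneration: int, timmature: int) -> int:
    """Days between contamination and the death-or-heal event.

    ``lt`` expresses the lethal time as a fraction of the mature-phase
    duration; the result is rounded to whole days with a floor of one day.
    """
    if not 0.0 < lt <= 1.0:
        raise ValueError(f"LT must be in (0, 1], got {lt}")
    return max(1, _round_half_up(lt * (tgeneration - timmature)))


@dataclass(frozen=True)
class SimParams:
    """Parameter set for one simulated pest-biocide system.

    Population traits
    -----------------
    N0 : founding population size (even; half males, half females).
    Tgeneration : individual lifespan in days.
    Pimmature : percent of the lifespan spent in the immature stage.

    Female traits
    -------------
    F : immature offspring surviving to maturity per female lifetime
        (immature mortality is folded into this number).
    Nmating : matings a female performs over her lifetime.

    Male traits
    -----------
    Csperm : sperm-competition regime, one of ``first``, ``last``, ``share``.
    Csterile, Cwild : mating competitiveness of sterile and wild males.
    ratio : sterile:wild release ratio used when none is given explicitly.

    Biocide traits
    --------------
    Ph : horizontal (mating) transmission probability.
    Pv : vertical (mother-to-offspring) transmission probability.
    Pc : male-to-male (lek contact) transmission probability.
    LT : lethal time as a fraction of the mature-phase duration.
    Virulence : probability of dying (vs. healing) when the lethal window ends.

    Experiment constants
    --------------------
    nx_multiplier : factor from N0 to the problematic size NX.
    success_fraction : suppression succeeds when N(t+1) < success_fraction*NX.
    max_ratio : cap of the release-ratio sweep.
    """

    N0: int = 30
    Tgeneration: int = 60
    Pimmature: float = 33.0
    F: float = 6.0
    Nmating: int = 3
    Csperm: str = "first"
    Csterile: float = 1.0
    Cwild: float = 1.0
    ratio: int = 0
    Ph: float = 0.25
    Pv: float = 0.25
    Pc: float = 0.0
    LT: float = 0.5
    Virulence: float = 0.5
    nx_multiplier: int = 1000
    success_fraction: float = 0.5
    max_ratio: int = 20

    def __post_init__(self) -> None:
        if self.N0 < 2 or self.N0 % 2:
            raise ValueError(
                f"N0 must be an even count >= 2 (equal sexes), got {self.N0}"
            )
        for name in ("Ph", "Pv", "Pc", "Virulence", "success_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.F < 1:
            raise ValueError(f"F must be >= 1, got {self.F}")
        if self.F == 2:
            raise ValueError(
                "F = 2 is not supported: the expected-generations formula "
                "divides by ln F - ln 2"
            )
        if self.Nmating < 1:
            raise ValueError(f"Nmating must be >= 1, got {self.Nmating}")
        if self.Csperm not in SPERM_REGIMES:
            raise ValueError(
                f"Csperm must be one of {SPERM_REGIMES}, got {self.Csperm!r}"
            )
        if self.Csterile <= 0 or self.Cwild <= 0:
            raise ValueError("competitiveness values must be positive")
        if self.ratio < 0:
            raise ValueError(f"ratio must be >= 0, got {self.ratio}")
        if self.nx_multiplier < 1:
            raise ValueError("nx_multiplier must be >= 1")
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")
        # These raise on out-of-range Tgeneration / Pimmature / LT / Nmating.
        t_imm = derive_timmature(self.Tgeneration, self.Pimmature)
        lethal_window(self.LT, self.Tgeneration, t_imm)
        if self.Nmating > self.Tgeneration - t_imm:
            raise ValueError(
                f"Nmating={self.Nmating} exceeds the adult span of "
                f"{self.Tgeneration - t_imm} days"
            )

    # -- derived constants -------------------------------------------------

    @property
    def Timmature(self) -> int:
        """Days spent immature."""
        return derive_timmature(self.Tgeneration, self.Pimmature)

    @property
    def adult_span(self) -> int:
        """Days spent mature (Tgeneration - Timmature)."""
        return self.Tgeneration - self.Timmature

    @property
    def NX(self) -> int:
        """Problematic population size (nx_multiplier times N0)."""
        return self.N0 * self.nx_multiplier

    @property
    def Tcontamination(self) -> int:
        """Lethal window in days."""
        return lethal_window(self.LT, self.Tgeneration, self.Timmature)

    def replace(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["Timmature"] = self.Timmature
        d["NX"] = self.NX
        d["Tcontamination"] = self.Tcontamination
        return d
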