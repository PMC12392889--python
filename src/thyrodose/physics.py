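"""Radioactive-decay primitives and exact time integrals.

Every cumulative-dose expression in this package reduces to integrals of
one or two decaying exponentials over an interval of days.  This module
provides those kernels in closed form, with a guarded small-rate branch,
plus the registry of the three fallout nuclides the dose model tracks.

Time is measured in days since the fallout onset epoch, 1986-04-28.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass

__all__ = [
    "DAYS_PER_YEAR",
    "EPOCH",
    "ADMINISTRATIVE_END",
    "FOLLOWUP_DAYS",
    "Nuclide",
    "NUCLIDES",
    "decay_constant",
    "integrated_exponential",
    "double_exponential_integral",
]

#: Fixed year length used for half-life conversion (Julian year).
DAYS_PER_YEAR = 365.25

#: Fallout onset; t = 0 for every dose integral.
EPOCH = datetime.date(1986, 4, 28)

#: Administrative end of follow-up.
ADMINISTRATIVE_END = datetime.date(2015, 12, 31)

#: Full follow-up horizon in days, computed from the calendar.
FOLLOWUP_DAYS = (ADMINISTRATIVE_END - EPOCH).days

# Below this value of rate*(t1-t0) the exponential integral switches to
# its linear limit, avoiding catastrophic cancellation.
_SMALL_RATE_PRODUCT = 1e-10

LN2 = math.log(2.0)


def decay_constant(half_life: float) -> float:
    """Physical decay constant ``ln(2)/T_half`` in 1/day.

    Parameters
    ----------
    half_life
        Physical half-life in days; must be positive.
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be positive, got {half_life!r}")
    return LN2 / half_life


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide with its physical half-life (days)."""

    name: str
    half_life: float

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"half_life must be positive, got {self.half_life!r}")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant in 1/day."""
        return decay_constant(self.half_life)


#: The three nuclides the model tracks.  I-131 dominates the acute milk and
#: inhalation pathways; Cs-134 and Cs-137 drive the protracted external and
#: ingestion pathways.  Half-lives: I-131 8.06 d, Cs-134 2.06 y, Cs-137 30.2 y.
NUCLIDES: dict[str, Nuclide] = {
    "I131": Nuclide("I131", 8.06),
    "Cs134": Nuclide("Cs134", 2.06 * DAYS_PER_YEAR),
    "Cs137": Nuclide("Cs137", 30.2 * DAYS_PER_YEAR),
}


def integrated_exponential(rate: float, t0: float, t1: float) -> float:
    """Integral of ``exp(-rate * s)`` over ``[t0, t1]`` in days.

    ``t1`` may be ``math.inf`` (requires ``rate > 0``).  For
    ``rate * (t1 - t0)`` below 1e-10 the series limit ``t1 - t0`` is
    returned to avoid cancellation; ``rate = 0`` always takes that branch.
    """
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate!r}")
    if t0 < 0:
        raise ValueError(f"t0 must be nonnegative, got {t0!r}")
    if t1 < t0:
        raise ValueError(f"t1 must be >= t0, got t0={t0!r}, t1={t1!r}")
    if math.isinf(t1):
        if rate == 0:
            raise ValueError("rate must be positive for an infinite horizon")
        return math.exp(-rate * t0) / rate
    if rate * (t1 - t0) < _SMALL_RATE_PRODUCT:
        # linear limit; exact for rate == 0
        return (t1 - t0) * math.exp(-rate * t0)
    return (math.exp(-rate * t0) - math.exp(-rate * t1)) / rate


def double_exponential_integral(
    w1: float,
    r1: float,
    w2: float,
    r2: float,
    extra_rate: float,
    t0: float,
    t1: float,
) -> float:
    """Integral of ``(w1 e^{-r1 s} + w2 e^{-r2 s}) e^{-extra_rate s}`` on ``[t0, t1]``.

    Shared kernel of the weathering (ground shine) and aggregate-transfer
    (body burden) time integrals: each is a two-component exponential
    decline multiplied by physical decay.
    """
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be nonnegative")
    if r1 < 0 or r2 < 0 or extra_rate < 0:
        raise ValueError("rates must be nonnegative")
    total = 0.0
    if w1 > 0:
        total += w1 * integrated_exponential(r1 + extra_rate, t0, t1)
    if w2 > 0:
        total += w2 * integrated_exponential(r2 + extra_rate, t0, t1)
    return total
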