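"""Absolute-age conversion and cave-system age bracketing.

Generations convert to years by multiplication with a generation time;
for amblyopsid cavefishes generation times are poorly known and are
carried as a (min, median, max) range, conventionally 3-15 years. A cave
system's age is then bracketed between the pseudogene-clock minimum (the
lineage must have been in the cave at least this long) and the
phylogenetic divergence maximum (it cannot have been there longer than
its separation from surface relatives).

Report values are rounded to 3 significant figures, half up; full
precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class GenerationTimeRange:
    """Years per generation: minimum, median and maximum estimates.

    The median is an explicit input, never derived from the endpoints.
    """

    t_min: float
    t_median: float
    t_max: float

    def __post_init__(self) -> None:
        if not 0 < self.t_min <= self.t_median <= self.t_max:
            raise ValueError(
                "generation times must satisfy 0 < t_min <= t_median <= t_max"
            )


@dataclass(frozen=True)
class AgeBracket:
    """Bounds on a cave-system age for one lineage, in years.

    ``clock_age_min``/``clock_age_max`` come from the pseudogene clock and
    generation-time range; ``divergence_upper`` from a dated phylogeny
    (None for an open upper bound). ``inconsistent`` flags a clock minimum
    exceeding the divergence maximum — flagged, never silently clipped.
    """

    lineage: str
    clock_age_min: float
    clock_age_max: float
    divergence_upper: float | None

    def __post_init__(self) -> None:
        if self.clock_age_min > self.clock_age_max:
            raise ValueError("clock_age_min exceeds clock_age_max")

    @property
    def bracket(self) -> tuple[float, float]:
        upper = (
            self.divergence_upper if self.divergence_upper is not None else math.inf
        )
        return (self.clock_age_min, upper)

    @property
    def inconsistent(self) -> bool:
        return (
            self.divergence_upper is not None
            and self.clock_age_min > self.divergence_upper
        )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, half up (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    shift = sig - 1 - math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(-shift)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def format_age(years: float, sig: int = 3) -> str:
    """Human-readable age: '2.25 Ma', '342 ka' or '120 yr'."""
    years = round_sig(years, sig)
    if years >= 1e6:
        return f"{round_sig(years / 1e6, sig):g} Ma"
    if years >= 1e3:
        return f"{round_sig(years / 1e3, sig):g} ka"
    return f"{years:g} yr"


def generations_to_years(g: float, t_gen: float) -> float:
    """Exact product g * t_gen (no rounding; format only in reports)."""
    if g < 0:
        raise ValueError("generations must be non-negative")
    if t_gen <= 0:
        raise ValueError("generation time must be positive")
    return g * t_gen


def age_range(
    g_range: tuple[float, float], times: GenerationTimeRange
) -> tuple[float, float]:
    """Cartesian min/max of a generation range times a generation-time range."""
    g_lo, g_hi = g_range
    if g_lo > g_hi:
        raise ValueError(f"generation range endpoints swapped: {g_range}")
    if g_lo < 0:
        raise ValueError("generations must be non-negative")
    corners = [
        generations_to_years(g, t)
        for g in (g_lo, g_hi)
        for t in (times.t_min, times.t_max)
    ]
    return min(corners), max(corners)


def cave_age_bracket(
    lineage: str,
    clock_range: tuple[float, float],
    node_age_upper: float | None,
) -> AgeBracket:
    """Bracket a cave-system age between clock minimum and divergence maximum.

    ``clock_range`` is in years (already converted); ``node_age_upper`` is
    the dated-tree upper bound in years, or None when no dated node is
    available (open upper bound).
    """
    lo, hi = clock_range
    return AgeBracket(
        lineage=lineage,
        clock_age_min=lo,
        clock_age_max=hi,
        divergence_upper=node_age_upper,
    )
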