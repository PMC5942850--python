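"""Nominal effective population size for serial growth-dilution cultures.

A daily cycle consists of ``k = floor(log2(dilution))`` complete doublings
from the post-dilution minimum up to the stationary census.  The nominal
effective size is the harmonic mean over the full within-cycle size ladder
reconstructed from stationary-phase censuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "generations_per_cycle",
    "complete_doublings",
    "total_generations",
    "size_ladder",
    "nominal_ne",
    "linkage_ne_hook",
    "CountSeries",
]


def generations_per_cycle(dilution: float) -> float:
    """Number of cell generations per growth-dilution cycle, log2(dilution)."""
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution}")
    return math.log2(dilution)


def complete_doublings(dilution: float) -> int:
    """Number of complete doublings per cycle, floor(log2(dilution))."""
    return math.floor(generations_per_cycle(dilution))


def total_generations(days: int, dilution: float) -> int:
    """Total generations after `days` daily transfer cycles, rounded to int."""
    if days < 0:
        raise ValueError("days must be non-negative")
    return round(days * generations_per_cycle(dilution))


def size_ladder(n_max: float, dilution: float) -> np.ndarray:
    """Within-cycle population sizes from post-dilution minimum to census.

    Returns ``[n_min * 2**0, ..., n_min * 2**k, n_max]`` with
    ``k = floor(log2(dilution))`` and ``n_min = n_max / dilution``; length
    ``k + 2``.  The final census entry accounts for the fractional last
    generation when ``log2(dilution)`` is not an integer.  ``dilution == 1``
    degenerates to the single-entry ladder ``[n_max]``.
    """
    if n_max <= 0:
        raise ValueError(f"n_max must be positive, got {n_max}")
    if dilution < 1:
        raise ValueError(f"dilution must be >= 1, got {dilution}")
    if dilution == 1:
        return np.array([float(n_max)])
    if n_max < dilution:
        raise ValueError(
            f"n_max ({n_max}) smaller than dilution fold ({dilution}): "
            "bottleneck would be < 1 cell"
        )
    k = complete_doublings(dilution)
    n_min = n_max / dilution
    ladder = n_min * np.power(2.0, np.arange(k + 1))
    return np.append(ladder, float(n_max))


@dataclass
class CountSeries:
    """Daily stationary-phase censuses for one population.

    NaN census entries (failed plate counts) are dropped and the day count
    adjusted accordingly.
    """

    n_max_by_day: Sequence[float]
    dilution: float
    population_id: str = ""
    days_used: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.n_max_by_day, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError("no usable census days")
        bad = np.nonzero(arr <= 0)[0]
        if bad.size:
            raise ValueError(f"non-positive census at day index {bad[0]}")
        self.n_max_by_day = arr
        self.days_used = int(arr.size)

    def ladders(self) -> np.ndarray:
        """(days_used, ladder_length) matrix of within-cycle sizes."""
        return np.vstack([size_ladder(n, self.dilution) for n in self.n_max_by_day])


def nominal_ne(series: CountSeries) -> float:
    """Harmonic mean of all within-cycle population sizes across sampled days.

    ``N_e = (D * ladder_length) / sum(1 / N)`` over every per-generation size
    of every sampled day ``D``.
    """
    ladders = series.ladders()
    return ladders.size / np.sum(1.0 / ladders)


def linkage_ne_hook(
    series: CountSeries,
    s: float,
    U_d: float,
    method: Callable[[CountSeries, float, float], float] | None = None,
) -> dict:
    """Pluggable interface for external linkage-corrected N_e estimators.

    The correction formulas live in external code; by default this records
    the parameters and reports that nothing was computed.  Supplying a
    callable ``method(series, s, U_d)`` returns its value unchanged.
    """
    out = {
        "s": s,
        "U_d": U_d,
        "population_id": series.population_id,
        "days_used": series.days_used,
    }
    if method is None:
        out.update(computed=False, value=None, note="external method; not implemented")
    else:
        out.update(computed=True, value=method(series, s, U_d), note="user-supplied method")
    return out
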