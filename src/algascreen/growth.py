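"""Growth kinetics from density/OD time series.

Cultures sampled every 24 h over seven days are summarised by the specific
growth rate mu (d^-1) and the biomass doubling ("generation") time in hours.
mu is the slope of ln(density) against time over the exponential phase; the
exponential window is found by an exhaustive scan of contiguous sub-windows
(see :func:`fit_exponential_window`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NoDoublingError",
    "GrowthCurve",
    "GrowthFit",
    "specific_growth_rate",
    "generation_time",
    "fit_exponential_window",
]

#: hours per day; mu is reported per day while times are recorded in hours
HOURS_PER_DAY = 24.0

_MEASURES = ("od550", "cell_count", "fluorescence")


class NoDoublingError(ValueError):
    """Raised when a generation time is requested for mu <= 0 (no doubling)."""


@dataclass(frozen=True)
class GrowthCurve:
    """One strain's density time series.

    times are in hours (strictly increasing); densities are OD550,
    cells/mL or relative fluorescence and must be strictly positive
    because the fit is taken on the log scale.
    """

    strain_id: str
    times: tuple[float, ...]
    densities: tuple[float, ...]
    measure: str = "od550"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        dens = tuple(float(d) for d in self.densities)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "densities", dens)
        if self.measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}, got {self.measure!r}")
        if len(times) != len(dens):
            raise ValueError("times and densities must have equal length")
        if len(times) < 3:
            raise ValueError("a growth curve needs at least 3 points")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(d <= 0 for d in dens):
            raise ValueError("densities must be strictly positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthFit:
    """Result of the log-linear exponential-phase fit for one strain."""

    strain_id: str
    mu: float  # specific growth rate, d^-1
    generation_time_h: float | None  # None when mu <= 0 (no doubling)
    window: tuple[int, int]  # [start, stop) indices of the points used
    r_squared: float
    n_points: int


def specific_growth_rate(n1: float, n2: float, t1: float, t2: float) -> float:
    """Two-point specific growth rate ln(n2/n1) / dt, in d^-1.

    Densities must be positive and t2 > t1 (hours). Negative values
    (culture decline) are returned as-is.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("densities must be strictly positive")
    if t2 <= t1:
        raise ValueError("t2 must be greater than t1")
    return math.log(n2 / n1) / ((t2 - t1) / HOURS_PER_DAY)


def generation_time(mu: float) -> float:
    """Biomass doubling time in hours, 24 ln2 / mu, for mu in d^-1.

    Raises :class:`NoDoublingError` for mu <= 0 — a non-growing culture
    has no doubling time (this is a distinct condition, not infinity).
    """
    if mu <= 0:
        raise NoDoublingError(f"mu = {mu} <= 0: culture never doubles")
    return HOURS_PER_DAY * math.log(2) / mu


def _loglinear(times: np.ndarray, log_dens: np.ndarray) -> tuple[float, float]:
    """Least-squares slope (per hour) and r^2 of log-density vs time.

    A window of constant density has zero total variance; by convention it
    returns slope 0 and r^2 = 0 (degenerate, never preferred by the scan).
    """
    t = times - times.mean()
    y = log_dens - log_dens.mean()
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        return 0.0, 0.0
    slope = float(t @ y) / float(t @ t)
    resid = y - slope * t
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, max(0.0, min(1.0, r2))


def fit_exponential_window(
    curve: GrowthCurve,
    min_points: int = 3,
    max_window_days: float = 3.0,
    r2_tol: float = 1e-9,
) -> GrowthFit:
    """Fit mu over the best exponential window of a growth curve.

    Every contiguous window with at least ``min_points`` points spanning at
    most ``max_window_days`` is scored by the r^2 of the least-squares line
    ln(density) vs time; the window with maximal r^2 wins, ties (within
    ``r2_tol``) broken by larger window, then earlier start. mu is the slope
    converted to d^-1; generation time follows from :func:`generation_time`.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    times = np.asarray(curve.times, dtype=float)
    log_dens = np.log(np.asarray(curve.densities, dtype=float))
    n = len(times)
    span_h = max_window_days * HOURS_PER_DAY

    best: tuple[float, int, int] | None = None  # (r2, n_points, start)
    best_slope = 0.0
    for start in range(n):
        for stop in range(start + min_points, n + 1):
            if times[stop - 1] - times[start] > span_h:
                break
            slope, r2 = _loglinear(times[start:stop], log_dens[start:stop])
            cand = (r2, stop - start, start)
            if best is None:
                best, best_slope = cand, slope
                continue
            if r2 > best[0] + r2_tol:
                better = True
            elif r2 < best[0] - r2_tol:
                better = False
            else:  # tied on r2: larger window, then earlier start
                better = (cand[1], -cand[2]) > (best[1], -best[2])
            if better:
                best, best_slope = cand, slope

    if best is None:  # no admissible window: fall back to the whole series
        raise ValueError(
            f"no window of >= {min_points} points fits within {max_window_days} days"
        )
    r2, n_points, start = best
    mu = best_slope * HOURS_PER_DAY
    gen_h = generation_time(mu) if mu > 0 else None
    return GrowthFit(
        strain_id=curve.strain_id,
        mu=mu,
        generation_time_h=gen_h,
        window=(start, start + n_points),
        r_squared=r2,
        n_points=n_points,
    )


def fit_table(curves: Sequence[GrowthCurve], **kwargs) -> "list[GrowthFit]":
    """Fit every curve; convenience wrapper used by the report layer."""
    return [fit_exponential_window(c, **kwargs) for c in curves]
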