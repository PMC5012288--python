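"""Copper toxicity bioassay statistics.

A 72-h static growth-response assay: cultures at a ladder of copper
concentrations (plus a zero-copper control) are followed by chlorophyll-a
fluorescence at 24-h intervals, in triplicate. Each replicate yields a
growth rate via the exponential-window fit; concentration means are
normalised to percent-of-control and summarised by percent inhibition

    %I = (C - X) / C * 100

with C the mean control rate and X the mean rate at the test concentration.
Between-strain tolerance differences use a pooled-variance Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import GrowthCurve, fit_exponential_window

__all__ = [
    "ControlFailureError",
    "DoseResponsePanel",
    "InhibitionResult",
    "percent_inhibition",
    "percent_of_control",
    "analyze_panel",
    "compare_to_reference",
]

_PANEL_COLUMNS = ("concentration_mg_L", "replicate", "time_h", "fluorescence")


class ControlFailureError(ValueError):
    """Raised when the zero-copper control did not grow (C <= 0)."""


def percent_inhibition(c_mean: float, x_mean: float) -> float:
    """%I = (C - X)/C * 100. Negative results (growth stimulation) pass through."""
    if c_mean <= 0:
        raise ControlFailureError(f"control mean rate {c_mean} <= 0")
    return (c_mean - x_mean) / c_mean * 100.0


def percent_of_control(c_mean: float, x_mean: float) -> float:
    """X/C * 100; complements percent_inhibition to exactly 100."""
    if c_mean <= 0:
        raise ControlFailureError(f"control mean rate {c_mean} <= 0")
    return x_mean / c_mean * 100.0


@dataclass(frozen=True)
class DoseResponsePanel:
    """Replicate fluorescence time courses over a copper concentration ladder.

    ``data`` is long format with columns concentration_mg_L, replicate,
    time_h, fluorescence. Concentration 0 (the control) must be present.
    """

    strain_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel data missing columns {missing}")
        if 0.0 not in set(self.data["concentration_mg_L"].astype(float)):
            raise ValueError(f"{self.strain_id}: no control (0 mg/L) series")

    @property
    def concentrations(self) -> list[float]:
        return sorted(set(self.data["concentration_mg_L"].astype(float)))

    def replicate_curves(self, concentration: float) -> list[GrowthCurve]:
        sub = self.data[self.data["concentration_mg_L"].astype(float) == concentration]
        curves = []
        for rep, grp in sub.groupby("replicate"):
            grp = grp.sort_values("time_h")
            curves.append(
                GrowthCurve(
                    strain_id=f"{self.strain_id}/c{concentration}/r{rep}",
                    times=tuple(grp["time_h"].astype(float)),
                    densities=tuple(grp["fluorescence"].astype(float)),
                    measure="fluorescence",
                )
            )
        return curves


@dataclass(frozen=True)
class InhibitionResult:
    """Per-concentration inhibition summary for one strain.

    ``per_concentration`` columns: concentration_mg_L, mean_rate,
    percent_of_control, percent_inhibition, no_growth. Replicate rates are
    kept for significance testing. no_growth forces %I = 100 / %control = 0.
    """

    strain_id: str
    per_concentration: pd.DataFrame
    replicate_rates: dict[float, tuple[float, ...]]

    def rates_at(self, concentration: float) -> tuple[float, ...]:
        return self.replicate_rates[concentration]


def _replicate_rates(
    panel: DoseResponsePanel, concentration: float, growth_window_h: float
) -> list[tuple[float, float, float]]:
    """(rate, first, last fluorescence) per replicate inside the assay window."""
    out = []
    for curve in panel.replicate_curves(concentration):
        mask = [t <= growth_window_h for t in curve.times]
        times = tuple(t for t, m in zip(curve.times, mask) if m)
        dens = tuple(d for d, m in zip(curve.densities, mask) if m)
        sub = GrowthCurve(curve.strain_id, times, dens, measure="fluorescence")
        fit = fit_exponential_window(sub)
        out.append((fit.mu, dens[0], dens[-1]))
    return out


def analyze_panel(
    panel: DoseResponsePanel, growth_window_h: float = 72.0
) -> InhibitionResult:
    """Growth rates, percent-of-control and %I across a copper ladder.

    Rates are exponential-window fits restricted to the 0..growth_window_h
    assay window. A concentration is flagged no_growth when its mean rate
    is <= 0 or mean final fluorescence does not exceed the initial; the
    flag forces %I = 100.
    """
    per_conc: dict[float, list[tuple[float, float, float]]] = {
        c: _replicate_rates(panel, c, growth_window_h) for c in panel.concentrations
    }
    c_mean = float(np.mean([r for r, _, _ in per_conc[0.0]]))
    if c_mean <= 0:
        raise ControlFailureError(
            f"{panel.strain_id}: control mean rate {c_mean:.4f} <= 0"
        )
    rows = []
    rates: dict[float, tuple[float, ...]] = {}
    for conc, reps in per_conc.items():
        mean_rate = float(np.mean([r for r, _, _ in reps]))
        first = float(np.mean([f for _, f, _ in reps]))
        last = float(np.mean([l for _, _, l in reps]))
        no_growth = mean_rate <= 0 or last <= first
        rows.append(
            {
                "concentration_mg_L": conc,
                "mean_rate": mean_rate,
                "percent_of_control": 0.0 if no_growth else percent_of_control(c_mean, mean_rate),
                "percent_inhibition": 100.0 if no_growth else percent_inhibition(c_mean, mean_rate),
                "no_growth": no_growth,
            }
        )
        rates[conc] = tuple(r for r, _, _ in reps)
    table = pd.DataFrame(rows).sort_values("concentration_mg_L").reset_index(drop=True)
    return InhibitionResult(
        strain_id=panel.strain_id, per_concentration=table, replicate_rates=rates
    )


def compare_to_reference(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-tailed Student's t-test (pooled variance) on replicate rates.

    Returns (t, p). With zero variance in both groups: equal means give
    (0, 1) by convention; unequal means give (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
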