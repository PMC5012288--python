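"""Biodiesel fuel-quality indices from compositional FAME profiles.

For a profile with wt% N_i, methyl-ester mass M_i (Da) and D_i double bonds
per species i:

    SV   = sum 560 N_i / M_i                (saponification value, mg KOH/g)
    IV   = sum 254 D_i N_i / M_i            (iodine value, g I2/100 g)
    CN   = sum (N_i/100)(-7.8 + 0.302 M_i - 20 D_i)   (component-weighted)
         or 46.3 + 5458/SV - 0.225 IV                  (aggregate variant)
    DU   = MUFA + 2 PUFA                    (degree of unsaturation, wt%)
    LCSF = 0.1 N(C16:0) + 0.5 N(C18:0) + N(C20:0) + 1.5 N(C22:0) + 2 N(C24:0)
    CFPP = 3.1417 LCSF - 16.477             (cold filter plugging point, degC)

The ASTM D675 biodiesel screen requires CN >= 47 and IV <= 120.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .fame import FameProfile, class_fractions, methyl_ester_mass
from .growth import GrowthFit

__all__ = [
    "ASTM_CN_MIN",
    "ASTM_IV_MAX",
    "BiodieselIndices",
    "AstmScreen",
    "ScreeningTable",
    "saponification_value",
    "iodine_value",
    "cetane_number",
    "degree_of_unsaturation",
    "long_chain_saturation_factor",
    "cold_filter_plugging_point",
    "compute_indices",
    "astm_screen",
    "screen_table",
    "round_half_away",
]

ASTM_CN_MIN = 47.0
ASTM_IV_MAX = 120.0

FAST_GROWER_MU = 1.0  # d^-1

# CFPP linear map from the long-chain saturation factor
_CFPP_SLOPE = 3.1417
_CFPP_INTERCEPT = -16.477

# LCSF weights on saturated long-chain species
_LCSF_WEIGHTS = {"C16:0": 0.1, "C18:0": 0.5, "C20:0": 1.0, "C22:0": 1.5, "C24:0": 2.0}

_CN_METHODS = ("component_weighted", "aggregate_sv_iv")


def _require_nonempty(profile: FameProfile) -> None:
    if not profile.abundances:
        raise ValueError(f"{profile.strain_id}: empty profile")


def saponification_value(profile: FameProfile) -> float:
    """SV = sum 560 N_i / M_i, in mg KOH per g of oil."""
    _require_nonempty(profile)
    return sum(560.0 * wt / methyl_ester_mass(sp) for sp, wt in profile.items())


def iodine_value(profile: FameProfile) -> float:
    """IV = sum 254 D_i N_i / M_i, in g I2 per 100 g of oil."""
    _require_nonempty(profile)
    return sum(
        254.0 * sp.double_bonds * wt / methyl_ester_mass(sp)
        for sp, wt in profile.items()
    )


def cetane_number(profile: FameProfile, method: str = "component_weighted") -> float:
    """Cetane number, by component-weighted (default) or aggregate SV/IV formula."""
    _require_nonempty(profile)
    if method == "component_weighted":
        return sum(
            (wt / 100.0) * (-7.8 + 0.302 * methyl_ester_mass(sp) - 20.0 * sp.double_bonds)
            for sp, wt in profile.items()
        )
    if method == "aggregate_sv_iv":
        return 46.3 + 5458.0 / saponification_value(profile) - 0.225 * iodine_value(profile)
    raise ValueError(f"unknown CN method {method!r}; expected one of {_CN_METHODS}")


def degree_of_unsaturation(profile: FameProfile) -> float:
    """DU = MUFA wt% + 2 * PUFA wt%; ranges from 0 to 200."""
    _, mufa, pufa = class_fractions(profile)
    return mufa + 2.0 * pufa


def long_chain_saturation_factor(profile: FameProfile) -> float:
    """Weighted wt% of saturated C16-C24 chains; predictor of cold-flow behaviour."""
    return sum(w * profile[label] for label, w in _LCSF_WEIGHTS.items())


def cold_filter_plugging_point(lcsf: float) -> float:
    """CFPP (degC) from the long-chain saturation factor, unrounded."""
    if lcsf < 0:
        raise ValueError("LCSF cannot be negative")
    return _CFPP_SLOPE * lcsf + _CFPP_INTERCEPT


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-layer convention, unlike round())."""
    factor = 10.0 ** ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    return math.copysign(r, x)


@dataclass(frozen=True)
class BiodieselIndices:
    """The six fuel-quality indices for one strain's FAME profile."""

    strain_id: str
    sv: float
    iv: float
    cn: float
    du: float
    lcsf: float
    cfpp: float
    cn_method: str = "component_weighted"

    @property
    def cfpp_reported(self) -> int:
        """CFPP rounded to the nearest integer degC, half away from zero."""
        return int(round_half_away(self.cfpp))


@dataclass(frozen=True)
class AstmScreen:
    """ASTM D675 pass flags: CN >= 47 and IV <= 120 (both inclusive)."""

    cn_pass: bool
    iv_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.cn_pass and self.iv_pass


def compute_indices(profile: FameProfile, cn_method: str = "component_weighted") -> BiodieselIndices:
    """All six indices for a profile; comparisons downstream use unrounded values."""
    lcsf = long_chain_saturation_factor(profile)
    return BiodieselIndices(
        strain_id=profile.strain_id,
        sv=saponification_value(profile),
        iv=iodine_value(profile),
        cn=cetane_number(profile, method=cn_method),
        du=degree_of_unsaturation(profile),
        lcsf=lcsf,
        cfpp=cold_filter_plugging_point(lcsf),
        cn_method=cn_method,
    )


def astm_screen(indices: BiodieselIndices) -> AstmScreen:
    return AstmScreen(cn_pass=indices.cn >= ASTM_CN_MIN, iv_pass=indices.iv <= ASTM_IV_MAX)


@dataclass(frozen=True)
class ScreeningTable:
    """Joint growth + fuel-quality screen over a strain collection.

    ``table`` has one row per strain with both inputs, ranked by
    (ASTM overall pass desc, mu desc); ``exclusions`` lists strains missing
    either input with the reason; ``counts`` are recomputed from the rows.
    """

    table: pd.DataFrame
    exclusions: Mapping[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        return {
            "n_strains": int(len(t)),
            "n_cn_pass": int(t["cn_pass"].sum()) if len(t) else 0,
            "n_iv_pass": int(t["iv_pass"].sum()) if len(t) else 0,
            "n_astm_pass": int(t["astm_pass"].sum()) if len(t) else 0,
            "n_fast_growers": int(t["fast_grower"].sum()) if len(t) else 0,
        }


def screen_table(
    profiles: Sequence[FameProfile],
    growth_fits: Sequence[GrowthFit],
    cn_method: str = "component_weighted",
) -> ScreeningTable:
    """Rank strains for feedstock potential from FAME profiles and growth fits.

    Strains present in only one of the two inputs are listed as exclusions,
    never silently dropped. Fast growers are mu >= 1.0 d^-1.
    """
    by_profile = {p.strain_id: p for p in profiles}
    by_fit = {f.strain_id: f for f in growth_fits}
    exclusions: dict[str, str] = {}
    rows = []
    for sid in sorted(set(by_profile) | set(by_fit)):
        if sid not in by_profile:
            exclusions[sid] = "no FAME profile"
            continue
        if sid not in by_fit:
            exclusions[sid] = "no growth fit"
            continue
        idx = compute_indices(by_profile[sid], cn_method=cn_method)
        screen = astm_screen(idx)
        fit = by_fit[sid]
        rows.append(
            {
                "strain": sid,
                "mu_per_day": fit.mu,
                "generation_time_h": fit.generation_time_h,
                "cn": idx.cn,
                "iv": idx.iv,
                "du": idx.du,
                "lcsf": idx.lcsf,
                "sv": idx.sv,
                "cfpp": idx.cfpp,
                "cfpp_reported": idx.cfpp_reported,
                "cn_pass": screen.cn_pass,
                "iv_pass": screen.iv_pass,
                "astm_pass": screen.overall_pass,
                "fast_grower": fit.mu >= FAST_GROWER_MU,
                "cn_method": cn_method,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "strain", "mu_per_day", "generation_time_h", "cn", "iv", "du",
            "lcsf", "sv", "cfpp", "cfpp_reported", "cn_pass", "iv_pass",
            "astm_pass", "fast_grower", "cn_method",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["astm_pass", "mu_per_day", "strain"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return ScreeningTable(table=table, exclusions=exclusions)
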