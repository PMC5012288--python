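"""Fatty-acid nomenclature, methyl-ester masses and compositional FAME profiles.

GC-MS FAME tables arrive as peak areas per fatty acid per strain, with a
nonadecanoate (C19:0) internal standard spiked at a known level. Profiles
used downstream are compositional: wt% of total identified FAME, summing
to 100 per strain. Fatty acids are named in CX:Y shorthand (X acyl carbons,
Y double bonds), optionally with an omega class ``(n-z)`` and a cis/trans
qualifier, e.g. ``C16:4(n-3)`` or ``C18:1-trans``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

__all__ = [
    "FattyAcidParseError",
    "FattyAcidSpecies",
    "FameProfile",
    "RawPeakTable",
    "parse_fatty_acid_notation",
    "methyl_ester_mass",
    "normalize_profile",
    "class_fractions",
    "quantify_against_standard",
]

# atomic masses (Da)
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999

_PROFILE_SUM_TOL = 1e-6

_GRAMMAR = re.compile(
    r"^(?:(?P<pre>cis|trans)-)?"  # prefix qualifier
    r"C(?P<carbons>\d+):(?P<db>\d+)"
    r"(?:\((?P<omega>n-\d+)\))?"
    r"(?:[\s-]?(?P<post>cis|trans))?$"
)


class FattyAcidParseError(ValueError):
    """Malformed fatty-acid shorthand; carries the position of failure."""

    def __init__(self, text: str, position: int, reason: str):
        self.text = text
        self.position = position
        super().__init__(f"cannot parse {text!r} at position {position}: {reason}")


@dataclass(frozen=True, order=True)
class FattyAcidSpecies:
    """A fatty acid identified by chain length, unsaturation and geometry."""

    carbons: int
    double_bonds: int
    omega: int | None = None  # the z of (n-z), first double-bond position
    geometry: str = "unspecified"  # cis | trans | unspecified

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("carbons must be >= 2")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"C{self.carbons}:{self.double_bonds}: a {self.carbons}-carbon chain "
                f"cannot hold {self.double_bonds} double bonds"
            )
        if self.geometry not in ("cis", "trans", "unspecified"):
            raise ValueError(f"bad geometry {self.geometry!r}")

    @property
    def label(self) -> str:
        """Canonical shorthand, e.g. ``C16:4(n-3)``, ``C18:1-trans``."""
        s = f"C{self.carbons}:{self.double_bonds}"
        if self.omega is not None:
            s += f"(n-{self.omega})"
        if self.geometry != "unspecified":
            s += f"-{self.geometry}"
        return s

    def __str__(self) -> str:
        return self.label


@lru_cache(maxsize=None)
def parse_fatty_acid_notation(text: str) -> FattyAcidSpecies:
    """Parse CX:Y shorthand (optional ``(n-z)`` omega class, cis/trans).

    Rejects malformed strings with the offset where matching failed, and
    chemically impossible unsaturation (Y > X/2).
    """
    stripped = text.strip()
    m = _GRAMMAR.match(stripped)
    if m is None:
        # locate the longest prefix that still could match, for the error
        pos = 0
        for pos in range(len(stripped), -1, -1):
            if any(_GRAMMAR.match(stripped[:pos] + tail)
                   for tail in ("", "0:0", ":0", "0")):
                break
        raise FattyAcidParseError(text, pos, "does not match C<X>:<Y>[(n-z)][cis|trans]")
    if m.group("pre") and m.group("post"):
        raise FattyAcidParseError(text, len(stripped), "duplicate cis/trans qualifier")
    geometry = m.group("pre") or m.group("post") or "unspecified"
    omega = m.group("omega")
    try:
        return FattyAcidSpecies(
            carbons=int(m.group("carbons")),
            double_bonds=int(m.group("db")),
            omega=int(omega.split("-")[1]) if omega else None,
            geometry=geometry,
        )
    except ValueError as exc:
        raise FattyAcidParseError(text, len(stripped), str(exc)) from None


def methyl_ester_mass(species: FattyAcidSpecies | str) -> float:
    """Molecular mass (Da) of the fatty acid methyl ester.

    A CX:Y acid esterifies to C(X+1) H(2X+2-2Y) O2; e.g. methyl palmitate
    (C16:0) is C17H34O2 = 270.46 Da. Geometry does not affect the mass.
    """
    if isinstance(species, str):
        species = parse_fatty_acid_notation(species)
    x, y = species.carbons, species.double_bonds
    return (x + 1) * _MASS_C + (2 * x + 2 - 2 * y) * _MASS_H + 2 * _MASS_O


@dataclass(frozen=True)
class FameProfile:
    """Compositional FAME profile: wt% of total identified FAME per species.

    Keys are canonical shorthand labels; values are >= 0 and sum to 100.
    """

    strain_id: str
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        canon = {}
        for label, value in self.abundances.items():
            sp = parse_fatty_acid_notation(label) if isinstance(label, str) else label
            v = float(value)
            if v < 0:
                raise ValueError(f"{self.strain_id}: negative abundance for {sp.label}")
            canon[sp.label] = canon.get(sp.label, 0.0) + v
        total = sum(canon.values())
        if abs(total - 100.0) > _PROFILE_SUM_TOL:
            raise ValueError(
                f"{self.strain_id}: abundances sum to {total}, expected 100"
            )
        object.__setattr__(self, "abundances", canon)

    def species(self) -> list[FattyAcidSpecies]:
        return [parse_fatty_acid_notation(lbl) for lbl in self.abundances]

    def __getitem__(self, label: str) -> float:
        return self.abundances.get(parse_fatty_acid_notation(label).label, 0.0)

    def items(self) -> Iterable[tuple[FattyAcidSpecies, float]]:
        for lbl, v in self.abundances.items():
            yield parse_fatty_acid_notation(lbl), v


@dataclass(frozen=True)
class RawPeakTable:
    """Raw GC-MS peaks for one strain, before compositional normalisation."""

    strain_id: str
    peaks: Mapping[str, float]
    internal_standard: str = "C19:0"
    standard_ppm: float = 100.0
    unidentified: Mapping[str, float] = field(default_factory=dict)


def normalize_profile(raw: RawPeakTable) -> FameProfile:
    """Drop the internal standard and rescale peaks to wt% summing to 100.

    Unidentified peaks (recorded separately on the table) never enter the
    profile; if present, the excluded fraction is reported via a warning.
    """
    std = parse_fatty_acid_notation(raw.internal_standard).label
    kept: dict[str, float] = {}
    for label, area in raw.peaks.items():
        canon = parse_fatty_acid_notation(label).label
        if canon == std:
            continue
        if area < 0:
            raise ValueError(f"{raw.strain_id}: negative peak for {canon}")
        kept[canon] = kept.get(canon, 0.0) + float(area)
    total = sum(kept.values())
    if total <= 0:
        raise ValueError(f"{raw.strain_id}: no non-zero peaks besides the standard")
    excluded = sum(raw.unidentified.values())
    if excluded > 0:
        frac = 100.0 * excluded / (excluded + total)
        warnings.warn(
            f"{raw.strain_id}: {frac:.1f}% of peak area unidentified and excluded",
            stacklevel=2,
        )
    return FameProfile(
        strain_id=raw.strain_id,
        abundances={k: 100.0 * v / total for k, v in kept.items()},
    )


def quantify_against_standard(raw: RawPeakTable) -> dict[str, float]:
    """Absolute concentrations (ppm) scaled by the internal-standard peak.

    Optional output; the biodiesel indices always use relative wt% instead.
    """
    std = parse_fatty_acid_notation(raw.internal_standard).label
    canon = {parse_fatty_acid_notation(k).label: float(v) for k, v in raw.peaks.items()}
    if std not in canon or canon[std] <= 0:
        raise ValueError(
            f"{raw.strain_id}: internal standard {std} missing or non-positive"
        )
    scale = raw.standard_ppm / canon[std]
    return {k: v * scale for k, v in canon.items() if k != std}


def class_fractions(profile: FameProfile) -> tuple[float, float, float]:
    """Partition wt% into (SFA, MUFA, PUFA) by double-bond count (0, 1, >=2)."""
    sfa = mufa = pufa = 0.0
    for sp, wt in profile.items():
        if sp.double_bonds == 0:
            sfa += wt
        elif sp.double_bonds == 1:
            mufa += wt
        else:
            pufa += wt
    return sfa, mufa, pufa
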