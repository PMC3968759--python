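"""Mineral stoichiometry: formulas, molar masses and element-to-Fe conversions.

Sequential-extraction schemes quantify iron bound in sulfide, carbonate and
phosphate minerals indirectly, by measuring the partner element (S, CO3, P)
and converting to Fe through the mineral's element mass ratio:

* amorphous monosulfide (FeS, mackinawite): Fe = 1.7 x S(AVS)
* pyrite (FeS2): Fe = S(pyritic) / 1.1, with pyritic S = Cr-reducible S - AVS S
* siderite (FeCO3): Fe = CO3(residual) / 1.07, residual = total - Ca - Mg carbonate
* vivianite (Fe3(PO4)2.8H2O): Fe = 2.7 x P(Fe-bound)

The rounded constants 1.7, 1.1, 1.07, 2.7 are the values conventionally used
in tailings/sediment work; each is the element mass ratio of the named mineral
rounded to 2-3 significant figures (e.g. Fe:S in FeS = 55.845/32.065 = 1.742).
``RatioSet(mode="paper")`` uses the rounded constants, ``mode="exact"``
recomputes them from the formulas in the mineral registry.

All conversion functions are linear and accept scalars or numpy arrays.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ATOMIC_MASS",
    "parse_formula",
    "molar_mass",
    "element_mass_ratio",
    "MineralSpecies",
    "MineralRegistry",
    "load_registry",
    "RatioSet",
    "fe_from_avs_s",
    "pyritic_s",
    "fe_from_pyritic_s",
    "fe_from_carbonate",
    "fe_from_p",
    "ClampWarning",
]

# IUPAC 2021 standard atomic weights (g/mol), abridged to the elements that
# occur in the registry minerals and common sediment phases.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.065,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Zn": 65.38,
}


class ClampWarning(UserWarning):
    """A physically impossible negative difference was clamped to zero."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)|(\()|(\))(\d*\.?\d*)")


def _parse_fragment(fragment: str) -> dict[str, float]:
    """Parse one dot-free formula fragment, e.g. ``Fe3(PO4)2``."""
    stack: list[dict[str, float]] = [{}]
    pos = 0
    for m in _TOKEN.finditer(fragment):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula fragment {fragment!r}")
        pos = m.end()
        elem, count, open_p, close_p, group_count = m.groups()
        if elem is not None:
            if elem not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {elem!r}")
            n = float(count) if count else 1.0
            stack[-1][elem] = stack[-1].get(elem, 0.0) + n
        elif open_p:
            stack.append({})
        else:  # close paren
            if len(stack) < 2:
                raise ValueError(f"unbalanced ')' in {fragment!r}")
            group = stack.pop()
            mult = float(group_count) if group_count else 1.0
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0.0) + n * mult
    if pos != len(fragment) or len(stack) != 1:
        raise ValueError(f"cannot parse formula fragment {fragment!r}")
    return stack[0]


def parse_formula(formula: str | Mapping[str, float]) -> dict[str, float]:
    """Parse a mineral formula into an element -> count mapping.

    Accepts hydrate/adduct notation with a dot and leading multipliers as
    written in the mineral literature, e.g. ``"5Fe2O3.9H2O"`` (ferrihydrite)
    or ``"Fe3(PO4)2.8H2O"`` (vivianite). A mapping passes through validated.
    """
    if isinstance(formula, Mapping):
        out: dict[str, float] = {}
        for el, n in formula.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n:
                out[el] = float(n)
        return out
    total: dict[str, float] = {}
    for part in str(formula).replace("·", ".").split("."):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(\d+\.?\d*)(?=[A-Z(])", part)
        mult = 1.0
        if m:
            mult = float(m.group(1))
            part = part[m.end():]
        for el, n in _parse_fragment(part).items():
            total[el] = total.get(el, 0.0) + n * mult
    if not total:
        raise ValueError(f"empty formula {formula!r}")
    return total


def molar_mass(formula: str | Mapping[str, float]) -> float:
    """Molar mass in g/mol of a formula (string or element->count mapping)."""
    counts = parse_formula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def element_mass_ratio(
    formula: str | Mapping[str, float], numerator: str, denominator: str
) -> float:
    """Mass ratio (n_num * M_num) / (n_den * M_den) of two elements in a formula.

    E.g. ``element_mass_ratio("FeS", "Fe", "S")`` = 55.845/32.065 = 1.742,
    the conversion factor from AVS sulfur to monosulfide-bound iron.
    """
    counts = parse_formula(formula)
    for el in (numerator, denominator):
        if el not in counts:
            raise ValueError(f"element {el!r} absent from formula")
    return (counts[numerator] * ATOMIC_MASS[numerator]) / (
        counts[denominator] * ATOMIC_MASS[denominator]
    )


@dataclass(frozen=True)
class MineralSpecies:
    """One entry of the mineral registry.

    Parameters
    ----------
    name : registry identifier, e.g. ``"goethite"``.
    formula : element -> count mapping (floats allowed, e.g. mackinawite FeS0.94
        is registered as ideal FeS).
    fe_oxidation_state : ``"II"``, ``"III"`` or ``"mixed"``.
    crystallinity : ``"amorphous"`` or ``"crystalline"``.
    fe2_fraction : fraction of the mineral's Fe that is ferrous; 1 for Fe(II)
        phases, 0 for Fe(III), intermediate for mixed-valence phases (green
        rust Fe3(OH)8 = FeII2FeIII -> 2/3; magnetite FeII FeIII2 -> 1/3).
    """

    name: str
    formula: dict[str, float]
    fe_oxidation_state: str
    crystallinity: str
    fe2_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.fe_oxidation_state not in ("II", "III", "mixed"):
            raise ValueError(f"bad oxidation state {self.fe_oxidation_state!r}")
        if self.crystallinity not in ("amorphous", "crystalline"):
            raise ValueError(f"bad crystallinity {self.crystallinity!r}")
        if not 0.0 <= self.fe2_fraction <= 1.0:
            raise ValueError("fe2_fraction must be in [0, 1]")
        if "Fe" not in self.formula:
            raise ValueError(f"mineral {self.name!r} contains no Fe")

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)

    @property
    def fe_mass_fraction(self) -> float:
        """Mass fraction of Fe in the mineral, in (0, 1]."""
        return self.formula["Fe"] * ATOMIC_MASS["Fe"] / self.molar_mass

    def mass_ratio(self, numerator: str, denominator: str) -> float:
        return element_mass_ratio(self.formula, numerator, denominator)


class MineralRegistry(dict):
    """Name -> :class:`MineralSpecies` mapping with a TSV loader.

    The shipped registry (``data/minerals.tsv``) covers the Fe phases relevant
    to anoxic clay tailings: ferric oxyhydroxides (ferrihydrite, goethite,
    lepidocrocite, akaganeite, hematite), magnetite, green rust, siderite,
    pyrite, amorphous FeS/mackinawite, vivianite, and a generic
    phyllosilicate-Fe placeholder for structural clay iron.
    """

    def add(self, species: MineralSpecies) -> None:
        self[species.name] = species

    @classmethod
    def from_tsv(cls, path_or_buf) -> "MineralRegistry":
        import pandas as pd

        df = pd.read_csv(path_or_buf, sep="\t", comment="#")
        reg = cls()
        for row in df.itertuples(index=False):
            reg.add(
                MineralSpecies(
                    name=row.name,
                    formula=parse_formula(row.formula),
                    fe_oxidation_state=row.fe_oxidation_state,
                    crystallinity=row.crystallinity,
                    fe2_fraction=float(row.fe2_fraction),
                )
            )
        return reg


def load_registry() -> MineralRegistry:
    """Load the mineral registry shipped with the package."""
    with resources.files("fefrac.data").joinpath("minerals.tsv").open("r") as fh:
        return MineralRegistry.from_tsv(fh)


#: Rounded conversion constants conventionally used in the field.
PAPER_CONSTANTS = {"r_avs": 1.7, "r_pyrite": 1.1, "r_siderite": 1.07, "r_vivianite": 2.7}


@dataclass(frozen=True)
class RatioSet:
    """The four element-mass conversion ratios used by the speciation chain.

    ``mode="paper"`` (default) fixes the conventional rounded constants
    (1.7, 1.1, 1.07, 2.7); ``mode="exact"`` recomputes each from the mineral
    formula. The two agree within 5% relative for every ratio.

    Attributes
    ----------
    r_avs : Fe-per-S mass ratio of FeS (Fe = r_avs * S_AVS).
    r_pyrite : S2-per-Fe mass ratio of FeS2 (Fe = S_pyritic / r_pyrite).
    r_siderite : CO3-per-Fe mass ratio of FeCO3 (Fe = CO3_residual / r_siderite).
    r_vivianite : Fe-per-P mass ratio of Fe3(PO4)2.8H2O (Fe = r_vivianite * P).
    """

    mode: str = "paper"
    r_avs: float = field(default=None)  # type: ignore[assignment]
    r_pyrite: float = field(default=None)  # type: ignore[assignment]
    r_siderite: float = field(default=None)  # type: ignore[assignment]
    r_vivianite: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "exact"):
            raise ValueError(f"mode must be 'paper' or 'exact', got {self.mode!r}")
        if self.mode == "paper":
            defaults = PAPER_CONSTANTS
        else:
            defaults = {
                "r_avs": element_mass_ratio("FeS", "Fe", "S"),
                "r_pyrite": element_mass_ratio("FeS2", "S", "Fe"),
                "r_siderite": element_mass_ratio("FeCO3", "C", "Fe")
                * molar_mass("CO3")
                / ATOMIC_MASS["C"],
                "r_vivianite": element_mass_ratio("Fe3(PO4)2.8H2O", "Fe", "P"),
            }
        for name, val in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, val)


def _require_nonneg(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


def fe_from_avs_s(s_avs, ratios: RatioSet = RatioSet()):
    """Fe (wt%) bound in amorphous monosulfide from AVS sulfur (wt% S)."""
    s = _require_nonneg(s_avs, "s_avs")
    out = ratios.r_avs * s
    return float(out) if out.ndim == 0 else out


def pyritic_s(s_crr, s_avs, *, warn: bool = True):
    """Pyritic sulfur = Cr-reducible S minus AVS S, clamped at zero.

    A raw negative difference (AVS exceeding total reduced S, possible with
    replicate noise) is unphysical; it is clamped and warned about.
    """
    crr = _require_nonneg(s_crr, "s_crr")
    avs = _require_nonneg(s_avs, "s_avs")
    raw = crr - avs
    if warn and np.any(raw < 0):
        warnings.warn(
            "AVS sulfur exceeds Cr-reducible sulfur; pyritic S clamped to 0",
            ClampWarning,
            stacklevel=2,
        )
    out = np.maximum(raw, 0.0)
    return float(out) if out.ndim == 0 else out


def fe_from_pyritic_s(s_pyr, ratios: RatioSet = RatioSet()):
    """Fe (wt%) bound in pyrite from pyritic sulfur (wt% S)."""
    s = _require_nonneg(s_pyr, "s_pyr")
    out = s / ratios.r_pyrite
    return float(out) if out.ndim == 0 else out


def fe_from_carbonate(co3_total, co3_ca, co3_mg, ratios: RatioSet = RatioSet(), *, warn: bool = True):
    """Fe (wt%) bound in siderite from the carbonate not held by Ca or Mg.

    The residual ``co3_total - co3_ca - co3_mg`` is attributed to FeCO3 and
    converted with the CO3:Fe mass ratio; a negative residual is clamped.
    """
    tot = _require_nonneg(co3_total, "co3_total")
    ca = _require_nonneg(co3_ca, "co3_ca")
    mg = _require_nonneg(co3_mg, "co3_mg")
    raw = tot - ca - mg
    if warn and np.any(raw < 0):
        warnings.warn(
            "Ca+Mg carbonate exceeds total carbonate; siderite CO3 clamped to 0",
            ClampWarning,
            stacklevel=2,
        )
    out = np.maximum(raw, 0.0) / ratios.r_siderite
    return float(out) if out.ndim == 0 else out


def fe_from_p(p_febound, ratios: RatioSet = RatioSet()):
    """Fe (wt%) bound in vivianite from Fe-bound phosphorus (wt% P)."""
    p = _require_nonneg(p_febound, "p_febound")
    out = ratios.r_vivianite * p
    return float(out) if out.ndim == 0 else out
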