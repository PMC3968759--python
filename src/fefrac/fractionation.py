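"""Mass-balance partitioning of sequential-extraction Fe measurements.

Four operationally defined extractions bracket the solid-phase iron pools of
an anoxic sediment or tailings sample (all concentrations wt% on an oven-dry
solid basis):

* ``fe_total`` — HNO3 acid digest; the environmentally available Fe.
* ``fe_dcb`` — dithionite-citrate-bicarbonate; crystalline + amorphous Fe
  (oxyhydr)oxides of both valences, sparing pyrite and siderite.
* ``fe_aod`` — ammonium oxalate in the dark; amorphous/poorly crystalline
  oxides plus akaganeite, magnetite, siderite, monosulfide and green rust.
* ``fe2_ferrozine`` — ferrozine-available ferrous iron (sorbed/exchangeable
  Fe(II) and ferrous oxyhydroxides such as green rust).

Combining these with mineral-bound Fe derived from partner-element
measurements (AVS and Cr-reducible S, residual carbonate, Fe-bound P) yields
the speciation chain::

    FeIII             = Fe_DCB - FeII_ferrozine
    amorphous FeIII   = Fe_AOD - Fe_siderite - Fe_AVS - FeII_ferrozine
    crystalline FeIII = FeIII - amorphous FeIII
    FeII              = Fe_total - FeIII
    crystalline FeII  = Fe_pyrite + Fe_vivianite + Fe_siderite
    amorphous FeII    = FeII - crystalline FeII

Every subtraction is clamped at zero (negative mineral masses are
unphysical); raw negative values are logged, and the clamps that break the
four-pool mass balance accumulate into ``clamp_residual`` so that

    fe3_amorphous + fe3_crystalline + fe2_crystalline + fe2_amorphous
        == fe_total + clamp_residual

holds exactly for any non-negative input. The internal chain is vectorised
over numpy arrays, so the Monte-Carlo uncertainty module reuses it unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .stoichiometry import (
    ClampWarning,
    RatioSet,
    fe_from_avs_s,
    fe_from_carbonate,
    fe_from_p,
    fe_from_pyritic_s,
    pyritic_s,
)

__all__ = [
    "Measurement",
    "SampleMetadata",
    "ExtractionMeasurements",
    "FeSpeciation",
    "ClampError",
    "fe3_total",
    "fe3_amorphous",
    "fe3_crystalline",
    "fe2_total",
    "fe2_crystalline",
    "fe2_amorphous",
    "speciate",
    "fes_share_of_amorphous_fe2",
]

MINERAL_FE_FIELDS = ("fe_fes", "fe_pyrite", "fe_siderite", "fe_vivianite")
#: Fields measured on whole (bulk) tailings rather than the separated solid
#: phase; rescaled by 1/solids_fraction before entering the chain.
WHOLE_BASIS_FIELDS = ("s_avs", "s_crr", "p_febound")


class ClampError(ValueError):
    """Raised in strict mode when a subtraction goes negative."""


class Measurement(NamedTuple):
    """Replicate summary of one measured quantity: (mean, sd, n)."""

    mean: float
    sd: float = 0.0
    n: int = 1

    def validate(self, name: str) -> None:
        if self.mean < 0:
            raise ValueError(f"{name}: mean must be non-negative")
        if self.sd < 0:
            raise ValueError(f"{name}: sd must be non-negative")
        if self.n < 1:
            raise ValueError(f"{name}: n must be >= 1")


@dataclass
class SampleMetadata:
    """Identity and context of one sample.

    ``treatment`` is one of ``initial`` / ``unamended`` / ``amended`` /
    ``custom``; ``port`` is the column sampling port (1-3) or None; ``eh_mv``
    is the redox potential in mV (annotation only, never computed on);
    ``solids_fraction`` converts whole-suspension measurements to the
    solid-phase basis (default 1.0 = no conversion).
    """

    sample_id: str
    treatment: str = "custom"
    port: Optional[int] = None
    eh_mv: Optional[float] = None
    solids_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.solids_fraction <= 1.0:
            raise ValueError("solids_fraction must be in (0, 1]")


@dataclass
class ExtractionMeasurements:
    """One sample's extraction chemistry; all concentrations wt% oven-dry.

    The four extraction totals are mandatory. For each accessory mineral of
    the crystalline-Fe(II) sum, either the raw partner-element measurement
    (``s_avs``/``s_crr``, carbonate triplet, ``p_febound``) or the
    pre-derived mineral-Fe column (``fe_fes`` ...) must be present; when both
    are supplied the pre-derived column takes precedence and the discrepancy
    is logged.
    """

    fe_total: Measurement
    fe2_ferrozine: Measurement
    fe_dcb: Measurement
    fe_aod: Measurement
    s_avs: Optional[Measurement] = None
    s_crr: Optional[Measurement] = None
    p_febound: Optional[Measurement] = None
    co3_total: Optional[Measurement] = None
    co3_ca: Optional[Measurement] = None
    co3_mg: Optional[Measurement] = None
    fe_fes: Optional[Measurement] = None
    fe_pyrite: Optional[Measurement] = None
    fe_siderite: Optional[Measurement] = None
    fe_vivianite: Optional[Measurement] = None

    def __post_init__(self) -> None:
        for name, meas in self.items():
            if meas is not None:
                if not isinstance(meas, Measurement):
                    meas = Measurement(*np.atleast_1d(meas))
                    setattr(self, name, meas)
                meas.validate(name)

    def items(self):
        for name in self.__dataclass_fields__:
            yield name, getattr(self, name)

    def consistency_flags(self, tolerance: float = 1e-9) -> list[str]:
        """Soft plausibility checks (flagged, never rejected)."""
        flags = []
        if self.fe2_ferrozine.mean > self.fe_dcb.mean + tolerance:
            flags.append("fe2_ferrozine exceeds fe_dcb")
        if self.fe_dcb.mean > self.fe_total.mean + tolerance:
            flags.append("fe_dcb exceeds fe_total")
        return flags


@dataclass
class FeSpeciation:
    """The derived Fe partition of one sample (all wt% oven-dry).

    ``fe2_components`` maps each crystalline-chain mineral (pyrite, siderite,
    vivianite) plus amorphous FeS to its Fe contribution. ``raw`` keeps the
    pre-clamp value of every subtraction for audit; ``clamp_residual`` is the
    total mass by which clamping inflated the four-pool sum over ``fe_total``.
    """

    sample_id: str
    fe_total: float
    fe3: float
    fe3_amorphous: float
    fe3_crystalline: float
    fe2: float
    fe2_crystalline: float
    fe2_amorphous: float
    fe2_components: dict[str, float]
    clamp_residual: float = 0.0
    raw: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def pools(self) -> dict[str, float]:
        return {
            "fe3_amorphous": self.fe3_amorphous,
            "fe3_crystalline": self.fe3_crystalline,
            "fe2_crystalline": self.fe2_crystalline,
            "fe2_amorphous": self.fe2_amorphous,
        }


# ---------------------------------------------------------------------------
# Elementary chain steps (scalar or array; clamped with warnings)
# ---------------------------------------------------------------------------


def _clamped(raw, label: str, warn: bool):
    if warn and np.any(np.asarray(raw) < 0):
        warnings.warn(f"{label} went negative and was clamped to 0", ClampWarning, stacklevel=3)
    out = np.maximum(raw, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def fe3_total(fe_dcb, fe2_ferrozine, *, warn: bool = True):
    """Total ferric iron: DCB-extractable Fe minus ferrozine-available Fe(II)."""
    return _clamped(np.asarray(fe_dcb, float) - fe2_ferrozine, "FeIII", warn)


def fe3_amorphous(fe_aod, fe_siderite, fe_fes, fe2_ferrozine, *, warn: bool = True):
    """Amorphous ferric iron: AOD Fe minus its ferrous interferences.

    Oxalate at pH ~3 also dissolves siderite, amorphous monosulfide and
    ferrozine-available Fe(II) (green rust, sorbed Fe2+), so those ferrous
    contributions are subtracted from the AOD pool.
    """
    raw = np.asarray(fe_aod, float) - fe_siderite - fe_fes - fe2_ferrozine
    return _clamped(raw, "amorphous FeIII", warn)


def fe3_crystalline(fe3, fe3_amorph, *, warn: bool = True):
    """Crystalline ferric iron: the FeIII not in the amorphous pool."""
    return _clamped(np.asarray(fe3, float) - fe3_amorph, "crystalline FeIII", warn)


def fe2_total(fe_total, fe3, *, warn: bool = True):
    """Total ferrous iron: environmentally available Fe minus FeIII."""
    return _clamped(np.asarray(fe_total, float) - fe3, "FeII", warn)


def fe2_crystalline(fe_pyrite, fe_vivianite, fe_siderite):
    """Crystalline ferrous iron: sum over pyrite, vivianite and siderite."""
    out = np.asarray(fe_pyrite, float) + fe_vivianite + fe_siderite
    return float(out) if np.ndim(out) == 0 else out


def fe2_amorphous(fe2, fe2_cryst, *, warn: bool = True):
    """Amorphous ferrous iron: the FeII not bound in crystalline minerals."""
    return _clamped(np.asarray(fe2, float) - fe2_cryst, "amorphous FeII", warn)


# ---------------------------------------------------------------------------
# Vectorised full chain
# ---------------------------------------------------------------------------


def chain(fe_total_, fe2_ferrozine_, fe_dcb_, fe_aod_, fe_fes_, fe_pyrite_, fe_siderite_, fe_vivianite_):
    """Run the full speciation chain on scalars or equal-shape arrays.

    Returns a dict of pools plus the pre-clamp raw values and the residual
    bookkeeping terms. Only three clamps can inflate the four-pool sum over
    ``fe_total`` and they are returned separately:

    * ``excess_amorphous`` — amorphous FeIII exceeding total FeIII,
    * ``deficit_fe2`` — FeIII exceeding total Fe,
    * ``deficit_fe2_amorphous`` — crystalline FeII exceeding total FeII.

    ``clamp_residual`` is their sum; ``clamped_any`` flags draws/samples in
    which any clamp (including the conservation-neutral FeIII and amorphous-
    FeIII clamps) fired.
    """
    fe_dcb_ = np.asarray(fe_dcb_, dtype=float)
    raw_fe3 = fe_dcb_ - fe2_ferrozine_
    fe3 = np.maximum(raw_fe3, 0.0)
    raw_fe3_am = np.asarray(fe_aod_, float) - fe_siderite_ - fe_fes_ - fe2_ferrozine_
    fe3_am = np.maximum(raw_fe3_am, 0.0)
    raw_fe3_cr = fe3 - fe3_am
    fe3_cr = np.maximum(raw_fe3_cr, 0.0)
    excess_amorphous = np.maximum(fe3_am - fe3, 0.0)
    raw_fe2 = np.asarray(fe_total_, float) - fe3
    fe2 = np.maximum(raw_fe2, 0.0)
    deficit_fe2 = np.maximum(-raw_fe2, 0.0)
    fe2_cr = np.asarray(fe_pyrite_, float) + fe_vivianite_ + fe_siderite_
    raw_fe2_am = fe2 - fe2_cr
    fe2_am = np.maximum(raw_fe2_am, 0.0)
    deficit_fe2_am = np.maximum(-raw_fe2_am, 0.0)
    clamp_residual = excess_amorphous + deficit_fe2 + deficit_fe2_am
    clamped_any = (
        (raw_fe3 < 0)
        | (raw_fe3_am < 0)
        | (raw_fe3_cr < 0)
        | (raw_fe2 < 0)
        | (raw_fe2_am < 0)
    )
    return {
        "fe_total": np.asarray(fe_total_, float),
        "fe3": fe3,
        "fe3_amorphous": fe3_am,
        "fe3_crystalline": fe3_cr,
        "fe2": fe2,
        "fe2_crystalline": fe2_cr,
        "fe2_amorphous": fe2_am,
        "clamp_residual": clamp_residual,
        "raw_fe3": raw_fe3,
        "raw_fe3_amorphous": raw_fe3_am,
        "raw_fe3_crystalline": raw_fe3_cr,
        "raw_fe2": raw_fe2,
        "raw_fe2_amorphous": raw_fe2_am,
        "clamped_any": clamped_any,
    }


def resolve_mineral_fe(
    m: ExtractionMeasurements,
    ratios: RatioSet,
    solids_fraction: float = 1.0,
    *,
    warn: bool = True,
) -> tuple[dict[str, float], list[str]]:
    """Derive per-mineral Fe (FeS, pyrite, siderite, vivianite) from a sample.

    Pre-derived mineral-Fe columns take precedence; otherwise the value is
    computed from the raw partner-element measurements, with whole-suspension
    quantities (S, P) rescaled by 1/solids_fraction to the solid-phase basis.
    Returns the mineral-Fe dict and a list of audit messages.
    """
    notes: list[str] = []
    scale = 1.0 / solids_fraction

    def pick(derived_name: str, raw_value, raw_desc: str) -> float:
        derived = getattr(m, derived_name)
        if derived is not None:
            if raw_value is not None and abs(derived.mean - raw_value) > 1e-9:
                notes.append(
                    f"{derived_name}: derived column {derived.mean:g} overrides "
                    f"value {raw_value:g} recomputed from {raw_desc}"
                )
            return derived.mean
        if raw_value is None:
            raise ValueError(
                f"missing input for {derived_name}: supply either the derived "
                f"column or the raw measurements ({raw_desc})"
            )
        return raw_value

    fes_raw = (
        fe_from_avs_s(m.s_avs.mean * scale, ratios) if m.s_avs is not None else None
    )
    pyr_raw = None
    if m.s_crr is not None and m.s_avs is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ClampWarning)
            s_pyr = pyritic_s(m.s_crr.mean * scale, m.s_avs.mean * scale)
        notes.extend(str(w.message) for w in caught)
        pyr_raw = fe_from_pyritic_s(s_pyr, ratios)
    sid_raw = None
    if m.co3_total is not None and m.co3_ca is not None and m.co3_mg is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ClampWarning)
            sid_raw = fe_from_carbonate(
                m.co3_total.mean, m.co3_ca.mean, m.co3_mg.mean, ratios
            )
        notes.extend(str(w.message) for w in caught)
    viv_raw = (
        fe_from_p(m.p_febound.mean * scale, ratios) if m.p_febound is not None else None
    )

    out = {
        "fes": pick("fe_fes", fes_raw, "s_avs"),
        "pyrite": pick("fe_pyrite", pyr_raw, "s_crr and s_avs"),
        "siderite": pick("fe_siderite", sid_raw, "co3_total/co3_ca/co3_mg"),
        "vivianite": pick("fe_vivianite", viv_raw, "p_febound"),
    }
    if warn:
        for note in notes:
            warnings.warn(note, ClampWarning if "clamp" in note else UserWarning, stacklevel=2)
    return out, notes


def speciate(
    meta: SampleMetadata,
    m: ExtractionMeasurements,
    ratios: RatioSet = RatioSet(),
    *,
    strict: bool = False,
) -> FeSpeciation:
    """Partition one sample's measurements into the four Fe speciation pools.

    Parameters
    ----------
    meta : sample identity; ``meta.solids_fraction`` rescales whole-suspension
        S and P measurements to the solid-phase basis.
    m : the extraction measurements (means are used; dispersion is handled by
        :mod:`fefrac.uncertainty`).
    ratios : conversion-constant set (``paper`` rounded or ``exact``).
    strict : if True, any negative subtraction raises :class:`ClampError`
        instead of clamping.
    """
    notes = list(m.consistency_flags())
    minerals, mineral_notes = resolve_mineral_fe(
        m, ratios, meta.solids_fraction, warn=False
    )
    notes.extend(mineral_notes)

    c = chain(
        m.fe_total.mean,
        m.fe2_ferrozine.mean,
        m.fe_dcb.mean,
        m.fe_aod.mean,
        minerals["fes"],
        minerals["pyrite"],
        minerals["siderite"],
        minerals["vivianite"],
    )
    for key in ("raw_fe3", "raw_fe3_amorphous", "raw_fe3_crystalline", "raw_fe2", "raw_fe2_amorphous"):
        if c[key] < 0:
            msg = f"{key.removeprefix('raw_')} = {float(c[key]):.6g} clamped to 0"
            if strict:
                raise ClampError(f"{meta.sample_id}: {msg}")
            notes.append(msg)

    return FeSpeciation(
        sample_id=meta.sample_id,
        fe_total=float(c["fe_total"]),
        fe3=float(c["fe3"]),
        fe3_amorphous=float(c["fe3_amorphous"]),
        fe3_crystalline=float(c["fe3_crystalline"]),
        fe2=float(c["fe2"]),
        fe2_crystalline=float(c["fe2_crystalline"]),
        fe2_amorphous=float(c["fe2_amorphous"]),
        fe2_components={
            "pyrite": minerals["pyrite"],
            "siderite": minerals["siderite"],
            "vivianite": minerals["vivianite"],
            "fes": minerals["fes"],
        },
        clamp_residual=float(c["clamp_residual"]),
        raw={
            "fe3": float(c["raw_fe3"]),
            "fe3_amorphous": float(c["raw_fe3_amorphous"]),
            "fe3_crystalline": float(c["raw_fe3_crystalline"]),
            "fe2": float(c["raw_fe2"]),
            "fe2_amorphous": float(c["raw_fe2_amorphous"]),
        },
        warnings=notes,
    )


def fes_share_of_amorphous_fe2(spec: FeSpeciation) -> Optional[float]:
    """Percent of amorphous FeII held as amorphous monosulfide (FeS).

    Returns None (undefined, not zero) when the amorphous FeII pool is empty.
    """
    if spec.fe2_amorphous <= 0:
        return None
    return 100.0 * spec.fe2_components["fes"] / spec.fe2_amorphous
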