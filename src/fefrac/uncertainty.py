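"""Replicate-uncertainty propagation through the speciation chain.

The extraction tables report each quantity as mean ± 1 sd over 2-4
replicates but give no covariances and no propagation rule. This module
propagates those dispersions by Monte-Carlo resampling: every measured
quantity is drawn independently from a normal(mean, sd) truncated at zero
(negative concentrations are unphysical), the full speciation chain runs on
each draw, and the per-pool draws are summarised. Because the chain is
affine wherever no clamp fires, a closed-form linear-propagation result
(:func:`linear_propagation`) exists for clamp-free inputs and serves as the
analytic cross-check for the sampler.

Draws are generated by a seeded :class:`numpy.random.Generator`; identical
(inputs, seed, n_draws) give bitwise-identical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .fractionation import ExtractionMeasurements, SampleMetadata, chain
from .stoichiometry import RatioSet

__all__ = ["PoolSummary", "SpeciationEnsemble", "propagate", "linear_propagation", "POOL_NAMES"]

POOL_NAMES = (
    "fe3",
    "fe3_amorphous",
    "fe3_crystalline",
    "fe2",
    "fe2_crystalline",
    "fe2_amorphous",
)


class PoolSummary(NamedTuple):
    mean: float
    sd: float
    lo: float
    hi: float


@dataclass
class SpeciationEnsemble:
    """Monte-Carlo summary of the speciation of one sample.

    ``pools`` maps each pool name to (mean, sd, lo, hi) where [lo, hi] is the
    central percentile interval at ``interval`` level; ``clamp_rate`` is the
    fraction of draws in which any zero-clamp fired anywhere in the chain.
    """

    sample_id: str
    pools: dict[str, PoolSummary]
    n_draws: int
    seed: int
    interval: float
    clamp_rate: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0, by vectorised rejection (exact)."""
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size)
    bad = x < 0
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = x < 0
    return x


def _source_fields(m: ExtractionMeasurements) -> list[str]:
    """The measured quantities that feed the chain for this sample.

    Pre-derived mineral-Fe columns take precedence over their raw
    partner-element inputs, mirroring :func:`fefrac.fractionation.speciate`.
    """
    fields = ["fe_total", "fe2_ferrozine", "fe_dcb", "fe_aod"]
    if m.fe_fes is not None:
        fields.append("fe_fes")
    else:
        fields.append("s_avs")
    if m.fe_pyrite is not None:
        fields.append("fe_pyrite")
    else:
        fields.extend(f for f in ("s_crr", "s_avs") if f not in fields)
    if m.fe_siderite is not None:
        fields.append("fe_siderite")
    else:
        fields.extend(["co3_total", "co3_ca", "co3_mg"])
    if m.fe_vivianite is not None:
        fields.append("fe_vivianite")
    else:
        fields.append("p_febound")
    for f in fields:
        if getattr(m, f) is None:
            raise ValueError(f"missing measurement {f!r}")
    return fields


def _chain_from_draws(
    draws: dict[str, np.ndarray], meta: SampleMetadata, ratios: RatioSet
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Map drawn measured quantities to chain pools (fully vectorised)."""
    scale = 1.0 / meta.solids_fraction
    extra_clamp = np.zeros_like(np.asarray(draws["fe_total"], float), dtype=bool)

    if "fe_fes" in draws:
        fes = draws["fe_fes"]
    else:
        fes = ratios.r_avs * draws["s_avs"] * scale
    if "fe_pyrite" in draws:
        pyr = draws["fe_pyrite"]
    else:
        raw = draws["s_crr"] * scale - draws["s_avs"] * scale
        extra_clamp |= raw < 0
        pyr = np.maximum(raw, 0.0) / ratios.r_pyrite
    if "fe_siderite" in draws:
        sid = draws["fe_siderite"]
    else:
        raw = draws["co3_total"] - draws["co3_ca"] - draws["co3_mg"]
        extra_clamp |= raw < 0
        sid = np.maximum(raw, 0.0) / ratios.r_siderite
    if "fe_vivianite" in draws:
        viv = draws["fe_vivianite"]
    else:
        viv = ratios.r_vivianite * draws["p_febound"] * scale

    c = chain(
        draws["fe_total"], draws["fe2_ferrozine"], draws["fe_dcb"], draws["fe_aod"],
        fes, pyr, sid, viv,
    )
    return c, np.asarray(c["clamped_any"]) | extra_clamp


def propagate(
    meta: SampleMetadata,
    m: ExtractionMeasurements,
    ratios: RatioSet = RatioSet(),
    n_draws: int = 10_000,
    seed: int = 0,
    interval: float = 0.95,
) -> SpeciationEnsemble:
    """Monte-Carlo propagation of replicate sds through the speciation chain.

    Each measured quantity is drawn ``n_draws`` times from an independent
    truncated normal at its reported (mean, sd); the chain runs per draw with
    all clamps active, and pool summaries plus the clamp rate are returned.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not 0.0 < interval < 1.0:
        raise ValueError("interval must be in (0, 1)")
    rng = np.random.default_rng(seed)
    draws = {
        f: _truncated_normal(rng, getattr(m, f).mean, getattr(m, f).sd, n_draws)
        for f in _source_fields(m)
    }
    c, clamped = _chain_from_draws(draws, meta, ratios)
    alpha = 100.0 * (1.0 - interval) / 2.0
    pools = {}
    for name in POOL_NAMES:
        x = np.asarray(c[name], float)
        sd = float(np.std(x, ddof=1)) if n_draws > 1 else 0.0
        lo, hi = np.percentile(x, [alpha, 100.0 - alpha])
        pools[name] = PoolSummary(float(np.mean(x)), sd, float(lo), float(hi))
    return SpeciationEnsemble(
        sample_id=meta.sample_id,
        pools=pools,
        n_draws=n_draws,
        seed=seed,
        interval=interval,
        clamp_rate=float(np.mean(clamped)),
    )


def linear_propagation(
    meta: SampleMetadata,
    m: ExtractionMeasurements,
    ratios: RatioSet = RatioSet(),
) -> dict[str, float]:
    """Closed-form linear error propagation on the unclamped affine chain.

    Valid cross-check for :func:`propagate` only when no clamp fires at the
    measurement means and the means sit several sds away from every clamp
    boundary (and from zero, so truncation is negligible). The chain is
    affine in the measured quantities there, so each pool sd is
    sqrt(sum_j (dpool/dx_j)^2 sd_j^2); the partials are obtained by
    finite differences, which are exact for an affine map.
    """
    fields = _source_fields(m)
    means = {f: np.array([getattr(m, f).mean]) for f in fields}
    base, clamped = _chain_from_draws(means, meta, ratios)
    if bool(clamped[0]):
        raise ValueError("a clamp fires at the means; linear propagation is invalid here")
    var = {name: 0.0 for name in POOL_NAMES}
    h = 1e-6
    for f in fields:
        sd = getattr(m, f).sd
        if sd == 0:
            continue
        bumped = dict(means)
        bumped[f] = means[f] + h
        c_up, _ = _chain_from_draws(bumped, meta, ratios)
        for name in POOL_NAMES:
            grad = (float(c_up[name][0]) - float(base[name][0])) / h
            var[name] += (grad * sd) ** 2
    return {name: float(np.sqrt(v)) for name, v in var.items()}
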