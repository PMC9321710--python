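"""Strain-evaluation quantities: yield, productivity, flux-sums, WT deltas.

Yield is product flux over carbon-source uptake (both as magnitudes,
optionally rescaled by a molar-mass ratio so a mass yield can be checked
against its theoretical bound of 1); productivity is yield times growth
rate, in h^-1.  Cofactor "production" is the summed positive production
terms of a metabolite across all reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lp import FluxState, SolverSettings, DEFAULT_SETTINGS, fba, fva, pfba
from .model import PathwayDefinition, StoichiometricModel, StrainDesign, apply_design

__all__ = [
    "StrainMetrics",
    "yield_of",
    "productivity_of",
    "productivity_range",
    "cofactor_flux_sum",
    "wt_variation",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class StrainMetrics:
    """Evaluated quantities for one strain (units noted per field).

    growth_rate: h^-1; product_flux and carbon_uptake: mmol gDW^-1 h^-1
    (carbon_uptake is the uptake magnitude); yield_value: dimensionless;
    productivity and productivity_range: h^-1; cofactor_production maps
    metabolite id -> mmol gDW^-1 h^-1.
    """

    growth_rate: float
    product_flux: float
    carbon_uptake: float
    yield_value: float
    productivity: float
    productivity_range: tuple[float, float] | None = None
    cofactor_production: Mapping[str, float] = field(default_factory=dict)
    n_knockouts: int = 0

    def wt_variations(self, wt: "StrainMetrics") -> dict[str, float]:
        """Percent change vs the wild type for the reported quantities."""
        out = {"growth_rate": wt_variation(self.growth_rate, wt.growth_rate)}
        for met, val in self.cofactor_production.items():
            out[met] = wt_variation(val, wt.cofactor_production.get(met, 0.0))
        return out


def yield_of(
    product_flux: float, carbon_uptake_flux: float, molar_mass_ratio: float = 1.0
) -> float:
    """Product yield: |product| / |uptake| * molar_mass_ratio.

    A zero product flux yields 0 regardless of uptake; a zero uptake with
    nonzero product is undefined and raises ``ValueError``.
    """
    if abs(product_flux) <= _ZERO_TOL:
        return 0.0
    if abs(carbon_uptake_flux) <= _ZERO_TOL:
        raise ValueError("yield undefined: zero carbon uptake with nonzero product")
    return abs(product_flux) / abs(carbon_uptake_flux) * molar_mass_ratio


def productivity_of(yield_value: float, growth_rate: float) -> float:
    """Productivity (h^-1): yield times growth rate."""
    if not (math.isfinite(yield_value) and math.isfinite(growth_rate)):
        raise ValueError("yield and growth rate must be finite")
    return yield_value * growth_rate


def productivity_range(
    model: StoichiometricModel,
    design: StrainDesign,
    pathways: Mapping[str, PathwayDefinition] | None = None,
    fraction_of_optimum: float = 1.0,
    molar_mass_ratio: float = 1.0,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> tuple[float, float]:
    """Min and max productivity (h^-1) of a strain's product reaction.

    The FVA interval of the product flux (at ``fraction_of_optimum`` of the
    strain's own growth optimum) is converted to productivity using the
    strain's growth rate and its parsimonious carbon-uptake magnitude.
    Raises ``ValueError`` if the strain is infeasible.
    """
    strain = apply_design(model, design, pathways)
    if strain.product_reaction is None or strain.carbon_source_exchange is None:
        raise ValueError("model must declare product and carbon-source reactions")
    growth_state = fba(strain, settings)
    if not growth_state.optimal:
        raise ValueError(f"strain is not feasible (FBA status {growth_state.status})")
    growth = growth_state.objective_value
    parsimonious = pfba(strain, settings=settings)
    uptake = abs(parsimonious.flux(strain, strain.carbon_source_exchange))
    ranges = fva(
        strain, fraction_of_optimum, reactions=[strain.product_reaction], settings=settings
    )
    p_lo, p_hi = ranges.range_of(strain, strain.product_reaction)
    vals = []
    for p in (p_lo, p_hi):
        if abs(p) <= _ZERO_TOL:
            y = 0.0
        else:
            y = yield_of(p, uptake, molar_mass_ratio)
        vals.append(productivity_of(y, growth))
    lo, hi = min(vals), max(vals)
    return lo, hi


def cofactor_flux_sum(
    model: StoichiometricModel, state: FluxState | np.ndarray, metabolite: str
) -> float:
    """Total production rate of a metabolite: sum_j max(0, S[met,j] * v_j)."""
    i = model.metabolite_index(metabolite)
    v = state.v if isinstance(state, FluxState) else np.asarray(state, float)
    if v is None:
        raise ValueError("flux state carries no flux vector")
    row = model.S.getrow(i).toarray().ravel()
    terms = row * v
    return float(np.sum(terms[terms > 0.0]))


def wt_variation(strain_value: float, wt_value: float) -> float:
    """Percent change of a strain quantity vs wild type: 100*(s - wt)/wt.

    Undefined for a zero wild-type value; returns NaN (tables render it as
    not-applicable).
    """
    if wt_value == 0.0:
        return math.nan
    return 100.0 * (strain_value - wt_value) / wt_value
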