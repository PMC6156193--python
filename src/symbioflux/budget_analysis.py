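"""Nitrogen budgeting and symbiont maintenance costs.

The nitrogen ledger converts each transported metabolite's flux into a flux
of nitrogen atoms (flux x N atoms per molecule) and asks what fraction of
the nitrogen a symbiont receives from the host comes back as essential
amino acids (EAAs) — the symbiont's N-recycling efficiency.  The balance
closes once the nitrogen retained in symbiont biomass is added back:
``N_in = N_out_EAA + N_out_other + N_biomass`` for elementally balanced
networks at steady state.

The maintenance cost of a symbiont is what the host gives up to grow it:
the difference in host growth yield between simulations with and without
that symbiont's biomass production, under nutrient uptakes capped at the
levels observed in the full model (so the comparison is not rescued by
extra feeding).  All other symbiont reactions stay open, so the host keeps
its access to symbiont-derived EAAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .exchange_analysis import ExchangeProfile
from .integration import MultiCompartmentModel
from .model_core import FormulaError, met_base_id
from .optimization import FluxSolution, solve_fba

__all__ = [
    "NitrogenLedger",
    "MaintenanceCostReport",
    "nitrogen_ledger",
    "maintenance_cost",
    "DEFAULT_CAPPED_NUTRIENTS",
]

#: main C/N/P/S sources whose uptake is frozen during cost simulations
DEFAULT_CAPPED_NUTRIENTS = (
    "glc", "glucose", "fru", "fructose",
    "nh3", "nh4", "ammonium", "ammonia",
    "pi", "phosphate", "so4", "sulfate",
)


@dataclass
class NitrogenLedger:
    """Nitrogen-atom fluxes through one symbiont (mmol-N gDW⁻¹ h⁻¹)."""

    compartment: str
    n_in: float
    n_out_eaa: float
    n_out_other: float
    n_biomass: float
    #: per-metabolite breakdown: base id -> (transport flux, N count, N flux)
    import_detail: Dict[str, Tuple[float, int, float]] = field(default_factory=dict)
    export_detail: Dict[str, Tuple[float, int, float]] = field(default_factory=dict)

    @property
    def n_out_total(self) -> float:
        return self.n_out_eaa + self.n_out_other

    @property
    def efficiency(self) -> float:
        """EAA-N returned to the host per unit N assimilated."""
        return self.n_out_eaa / self.n_in if self.n_in > 0 else float("nan")

    @property
    def closure_residual(self) -> float:
        return self.n_in - self.n_out_total - self.n_biomass


def _species_formula_n(model: MultiCompartmentModel, base: str) -> Optional[int]:
    """N atoms per molecule of ``base``; None when no copy has a formula."""
    for met in model.metabolites.values():
        if met.base_id == base and met.formula:
            return met.elements().get("N", 0)
    return None


def nitrogen_ledger(
    model: MultiCompartmentModel,
    profile: ExchangeProfile,
    solution: FluxSolution,
) -> NitrogenLedger:
    """Build the nitrogen ledger for one symbiont compartment.

    Every metabolite in the thresholded exchange profile must carry an
    elemental formula; missing formulas are an error (silently counting
    zero would corrupt the budget).  Biomass N retention is the N content
    of the precursors the compartment's biomass reaction consumes, times
    the realized biomass flux.
    """
    missing = [
        m
        for m in list(profile.imports) + list(profile.exports)
        if _species_formula_n(model, m) is None
    ]
    if missing:
        raise FormulaError(
            f"transported metabolites without elemental formulas in "
            f"{profile.compartment!r}: {sorted(set(missing))}"
        )

    species_tags = {}
    for met in model.metabolites.values():
        species_tags.setdefault(met.base_id, set()).update(met.tags)

    import_detail: Dict[str, Tuple[float, int, float]] = {}
    n_in = 0.0
    for base, flux in profile.imports.items():
        n = _species_formula_n(model, base)
        import_detail[base] = (flux, n, flux * n)
        n_in += flux * n

    export_detail: Dict[str, Tuple[float, int, float]] = {}
    n_out_eaa = 0.0
    n_out_other = 0.0
    for base, flux in profile.exports.items():
        n = _species_formula_n(model, base)
        export_detail[base] = (flux, n, flux * n)
        if "eaa" in species_tags.get(base, set()):
            n_out_eaa += flux * n
        else:
            n_out_other += flux * n

    n_biomass = 0.0
    biomass_id = model.biomass_reactions.get(profile.compartment)
    if biomass_id is not None:
        rxn = model.reactions[biomass_id]
        v = solution.flux.get(biomass_id, 0.0)
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if coeff < 0 and met.formula:
                n_biomass += (-coeff) * met.elements().get("N", 0) * v

    return NitrogenLedger(
        compartment=profile.compartment,
        n_in=n_in,
        n_out_eaa=n_out_eaa,
        n_out_other=n_out_other,
        n_biomass=n_biomass,
        import_detail=import_detail,
        export_detail=export_detail,
    )


@dataclass
class MaintenanceCostReport:
    """Host growth with/without one symbiont's biomass production."""

    symbiont: str
    host_growth_full: float
    host_growth_symbiont_off: float
    status_off: str = "optimal"
    capped_uptakes: Dict[str, float] = field(default_factory=dict)

    @property
    def cost_absolute(self) -> float:
        """Growth the host forgoes by building symbiont biomass."""
        return self.host_growth_symbiont_off - self.host_growth_full

    @property
    def cost_relative(self) -> float:
        """Absolute cost as a fraction of full-model host growth."""
        if self.host_growth_full == 0:
            return float("nan")
        return self.cost_absolute / self.host_growth_full


def maintenance_cost(
    model: MultiCompartmentModel,
    symbiont: str,
    capped_nutrients: Iterable[str] = DEFAULT_CAPPED_NUTRIENTS,
) -> MaintenanceCostReport:
    """Cost to the host of maintaining one symbiont's biomass.

    Procedure: (1) solve the full model (both biomass floors active) and
    record the uptake fluxes of the main C/N/P/S nutrients; (2) freeze
    those uptakes as caps, zero the target symbiont's biomass reaction
    (bounds (0, 0)) while the other symbiont keeps its floor and every
    non-biomass reaction stays open; (3) re-solve and report both growth
    yields.  An infeasible symbiont-off model is reported through
    ``status_off`` rather than raised.
    """
    if symbiont not in model.symbiont_compartments:
        raise ValueError(
            f"{symbiont!r} is not a symbiont compartment of {model.id!r} "
            f"(have {model.symbiont_compartments})"
        )
    full = solve_fba(model)
    if not full.optimal:
        raise RuntimeError(f"full model is not optimal (status={full.status})")

    capped = set(capped_nutrients)
    observed: Dict[str, float] = {}
    perturbed = model.copy()
    for rxn in perturbed.exchange_reactions():
        base = met_base_id(next(iter(rxn.stoichiometry)))
        if base in capped:
            uptake = max(0.0, -full.flux[rxn.id])
            observed[base] = uptake
            rxn.lower_bound = -uptake

    biomass_id = perturbed.biomass_reactions.get(symbiont)
    if biomass_id is None:
        raise ValueError(f"no biomass reaction registered for {symbiont!r}")
    rxn = perturbed.reactions[biomass_id]
    rxn.lower_bound = 0.0
    rxn.upper_bound = 0.0

    off = solve_fba(perturbed)
    return MaintenanceCostReport(
        symbiont=symbiont,
        host_growth_full=full.objective_value,
        host_growth_symbiont_off=off.objective_value if off.optimal else float("nan"),
        status_off=off.status,
        capped_uptakes=observed,
    )
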