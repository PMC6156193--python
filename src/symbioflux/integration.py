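"""Assembly of the three-compartment host + two-symbiont model.

The stages mirror the order the pipeline runs them:

1. :func:`normalize_expression` turns replicate TPM values into integer
   expression levels (lowest nonzero mean = 1).
2. :func:`apply_expression_bounds` converts levels into host reaction flux
   bounds through the gene-protein-reaction (GPR) rules (OR = sum of isozyme
   capacities, AND = min over complex subunits); reactions with no matching
   transcript get a default bound of 10 mmol gDW⁻¹ h⁻¹.
3. :func:`build_multicompartment` merges the organism models, adds 1:1
   cost-free transport reactions and an external compartment with exchange
   reactions.
4. :func:`apply_medium` opens uptake only for the configured nutrients
   (O₂ capped at 20, others at 100 by default) and closes amino-acid uptake.
5. :func:`build_objective` derives host biomass coefficients from the
   amino-acid composition of insect protein plus small B-vitamin terms.
6. :func:`fix_symbiont_biomass` pins each symbiont's biomass reaction to a
   growth floor (default 0.01 mmol gDW⁻¹ h⁻¹), the "equal biomass
   proportions" assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model_core import (
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    met_base_id,
    met_compartment,
)
from .model_io import ExpressionTable

__all__ = [
    "NormalizedExpression",
    "MediumSpec",
    "BiomassSpec",
    "MultiCompartmentModel",
    "TransportEntry",
    "normalize_expression",
    "apply_expression_bounds",
    "build_multicompartment",
    "apply_medium",
    "build_objective",
    "fix_symbiont_biomass",
    "AMINO_ACID_MW",
]

DEFAULT_HOST_BOUND = 10.0       # mmol gDW-1 h-1, reactions with no transcript match
DEFAULT_UPTAKE_CAP = 100.0      # mmol gDW-1 h-1 per nutrient
DEFAULT_O2_CAP = 20.0           # aerobic conditions
DEFAULT_BIOMASS_FLOOR = 0.01    # mmol gDW-1 h-1 per symbiont
DEFAULT_VITAMIN_COEFF = 5e-5    # B-vitamin biomass coefficient

#: residue-free molecular weights (g/mol) of the 20 proteinogenic amino acids
AMINO_ACID_MW: Dict[str, float] = {
    "alanine": 89.09, "arginine": 174.20, "asparagine": 132.12,
    "aspartate": 133.10, "cysteine": 121.16, "glutamate": 147.13,
    "glutamine": 146.15, "glycine": 75.07, "histidine": 155.15,
    "isoleucine": 131.17, "leucine": 131.17, "lysine": 146.19,
    "methionine": 149.21, "phenylalanine": 165.19, "proline": 115.13,
    "serine": 105.09, "threonine": 119.12, "tryptophan": 204.23,
    "tyrosine": 181.19, "valine": 117.15,
}


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedExpression:
    """Integer expression level per gene; the lowest expressed gene is 1."""

    levels: Dict[str, int]

    def __post_init__(self) -> None:
        if self.levels and min(self.levels.values()) < 1:
            raise ValueError("normalized expression levels must be >= 1")

    def get(self, gene: str) -> Optional[int]:
        return self.levels.get(gene)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def normalize_expression(table: ExpressionTable) -> NormalizedExpression:
    """TPM table -> integer levels.

    Zero-TPM genes are first assigned, per replicate, the lowest nonzero TPM
    of that replicate; each gene's mean across replicates is then divided by
    the lowest nonzero mean and rounded half-up, so the floor level is 1.
    """
    df = table.data.copy()
    if not (df.values > 0).any():
        raise ValueError("expression table is all zero; no nonzero floor exists")
    for col in df.columns:
        nz = df.loc[df[col] > 0, col]
        if len(nz):
            df.loc[df[col] == 0, col] = nz.min()
    means = df.mean(axis=1)
    floor = means[means > 0].min()
    levels = {
        gene: max(1, _round_half_up(m / floor)) for gene, m in means.items()
    }
    return NormalizedExpression(levels)


# ---------------------------------------------------------------------------
# expression-derived reaction bounds
# ---------------------------------------------------------------------------

def _evaluate_gpr(rule: str, levels: Dict[str, int]) -> Tuple[float, bool]:
    """GPR capacity: OR = sum, AND = min; genes missing from ``levels`` are 0.

    Returns (capacity, matched_any_gene).  Parsing reuses cobrapy's
    ast-based GPR parser.
    """
    import ast

    from cobra.core.gene import GPR

    gpr = GPR.from_string(rule)
    matched = {"any": False}

    def walk(node) -> float:
        if isinstance(node, ast.BoolOp):
            values = [walk(v) for v in node.values]
            if isinstance(node.op, ast.Or):
                return float(sum(values))
            return float(min(values))
        if isinstance(node, ast.Name):
            if node.id in levels:
                matched["any"] = True
                return float(levels[node.id])
            return 0.0
        raise ValueError(f"unsupported GPR node {type(node).__name__} in {rule!r}")

    if gpr.body is None:
        return 0.0, False
    return walk(gpr.body), matched["any"]


def apply_expression_bounds(
    model: MetabolicModel,
    expr: NormalizedExpression,
    default_bound: float = DEFAULT_HOST_BOUND,
) -> MetabolicModel:
    """Set reaction bounds from transcript levels (E-Flux-style).

    For gene-associated reactions whose GPR matches at least one measured
    gene, ub = evaluated capacity and lb = -ub for reversible reactions
    (0 otherwise).  Orphan reactions and reactions with no matching
    transcript get ``default_bound`` the same way.  Exchange, transport and
    biomass reactions are left untouched.
    """
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind in {"exchange", "transport", "biomass", "objective"}:
            continue
        reversible = rxn.reversible
        if rxn.gene_association:
            capacity, matched = _evaluate_gpr(rxn.gene_association, expr.levels)
            ub = float(capacity) if matched else default_bound
        else:
            ub = default_bound
        rxn.upper_bound = ub
        rxn.lower_bound = -ub if reversible else 0.0
    return out


# ---------------------------------------------------------------------------
# multi-compartment assembly
# ---------------------------------------------------------------------------

@dataclass
class TransportEntry:
    """One cost-free 1:1 transport: ``metabolite`` moves donor -> recipient."""

    metabolite: str
    donor: str
    recipient: str
    reversible: bool = True


@dataclass
class MultiCompartmentModel(MetabolicModel):
    """Merged model with per-reaction provenance and a transport registry."""

    provenance: Dict[str, str] = field(default_factory=dict)
    #: (base metabolite id, donor compartment, recipient compartment) -> reaction id
    transport_registry: Dict[Tuple[str, str, str], str] = field(default_factory=dict)
    #: compartment id -> biomass reaction id
    biomass_reactions: Dict[str, str] = field(default_factory=dict)
    external_compartment: str = "e"
    host_compartment: str = ""
    symbiont_compartments: List[str] = field(default_factory=list)

    def transports_touching(self, compartment: str) -> List[str]:
        return [
            rid
            for (met, donor, recipient), rid in self.transport_registry.items()
            if compartment in (donor, recipient)
        ]

    def transport_reaction_ids(self) -> List[str]:
        return list(self.transport_registry.values())


def _exchange_id(base: str) -> str:
    return f"EX_{base}"


def build_multicompartment(
    host: MetabolicModel,
    symA: MetabolicModel,
    symB: MetabolicModel,
    transport_spec: Sequence[TransportEntry],
    external_compartment: str = "e",
) -> MultiCompartmentModel:
    """Merge three organism models into one model linked by transports.

    Each source model must live in a single compartment of its own; the
    merged model keeps every source reaction with provenance, adds one
    1:1 cost-free transport reaction per spec entry, and creates the
    external compartment with an export-positive exchange reaction
    (``met[e] -> ∅``) for every external metabolite.  Exchanges start
    closed for uptake; :func:`apply_medium` opens the nutrients.
    """
    sources = [("host", host), ("symA", symA), ("symB", symB)]
    comps: List[str] = []
    for role, m in sources:
        cs = {c for c in m.compartments}
        if len(cs) != 1:
            raise ModelIntegrityError(
                f"{role} model {m.id!r} must occupy exactly one compartment, has {sorted(cs)}"
            )
        comps.append(cs.pop())
    if len(set(comps)) != 3 or external_compartment in comps:
        raise ModelIntegrityError(
            f"compartment ids must be disjoint (got {comps} + external "
            f"{external_compartment!r})"
        )
    host_c, symA_c, symB_c = comps

    merged = MultiCompartmentModel(
        id=f"{host.id}+{symA.id}+{symB.id}",
        external_compartment=external_compartment,
        host_compartment=host_c,
        symbiont_compartments=[symA_c, symB_c],
    )
    role_of = {host_c: "host", symA_c: "symA", symB_c: "symB"}
    for (role, m), comp in zip(sources, comps):
        for met in m.metabolites.values():
            merged.add_metabolite(
                Metabolite(met.id, met.name, met.formula, met.compartment_id, set(met.tags))
            )
        for rxn in m.reactions.values():
            merged.add_reaction(
                Reaction(
                    id=rxn.id,
                    name=rxn.name,
                    stoichiometry=dict(rxn.stoichiometry),
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    gene_association=rxn.gene_association,
                    kind=rxn.kind,
                    subsystem=rxn.subsystem,
                )
            )
            merged.provenance[rxn.id] = role
            if rxn.kind == "biomass":
                merged.biomass_reactions[comp] = rxn.id
        merged.objective.update(m.objective)

    if external_compartment not in merged.compartments:
        merged.compartments.append(external_compartment)

    for entry in transport_spec:
        base = entry.metabolite
        ids = {}
        for comp in (entry.donor, entry.recipient):
            mid = f"{base}[{comp}]"
            if mid not in merged.metabolites:
                if comp == external_compartment:
                    template = _find_species(merged, base)
                    merged.add_metabolite(
                        Metabolite(
                            id=mid,
                            name=template.name if template else base,
                            formula=template.formula if template else "",
                            compartment_id=comp,
                            tags=set(template.tags) if template else set(),
                        )
                    )
                else:
                    raise ModelIntegrityError(
                        f"transport endpoint missing: metabolite {base!r} not "
                        f"declared in compartment {comp!r}"
                    )
            ids[comp] = mid
        rid = f"T_{base}_{entry.donor}_{entry.recipient}"
        merged.add_reaction(
            Reaction(
                id=rid,
                name=f"{base} transport {entry.donor}->{entry.recipient}",
                stoichiometry={ids[entry.donor]: -1.0, ids[entry.recipient]: +1.0},
                lower_bound=-1000.0 if entry.reversible else 0.0,
                upper_bound=1000.0,
                kind="transport",
            )
        )
        merged.provenance[rid] = "transport"
        merged.transport_registry[(base, entry.donor, entry.recipient)] = rid

    # export-positive exchange for every external species; uptake closed
    for met in list(merged.metabolites.values()):
        if met.compartment_id != external_compartment:
            continue
        rid = _exchange_id(met.base_id)
        if rid in merged.reactions:
            continue
        merged.add_reaction(
            Reaction(
                id=rid,
                name=f"{met.base_id} exchange",
                stoichiometry={met.id: -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="exchange",
            )
        )
        merged.provenance[rid] = "external"
    merged.validate()
    return merged


def _find_species(model: MetabolicModel, base: str) -> Optional[Metabolite]:
    for met in model.metabolites.values():
        if met.base_id == base:
            return met
    return None


# ---------------------------------------------------------------------------
# medium
# ---------------------------------------------------------------------------

@dataclass
class MediumSpec:
    """Nutrient uptake caps for the external medium.

    ``uptake_caps`` lists the allowed nutrients (base metabolite ids) with
    their maximum uptake flux; ``None`` entries get ``default_uptake_cap``.
    Metabolites carrying an excluded tag (amino acids) never open for
    uptake.
    """

    uptake_caps: Dict[str, Optional[float]] = field(default_factory=dict)
    default_uptake_cap: float = DEFAULT_UPTAKE_CAP
    o2_cap: float = DEFAULT_O2_CAP
    o2_id: str = "o2"
    excluded_tags: Set[str] = field(default_factory=lambda: {"eaa"})

    def cap_for(self, base: str) -> Optional[float]:
        if base == self.o2_id and (base in self.uptake_caps or self.o2_cap is not None):
            return self.o2_cap
        if base in self.uptake_caps:
            cap = self.uptake_caps[base]
            return self.default_uptake_cap if cap is None else cap
        return None

    @property
    def nutrients(self) -> List[str]:
        names = list(self.uptake_caps)
        if self.o2_id not in names:
            names.append(self.o2_id)
        return names


def apply_medium(model: MultiCompartmentModel, medium: MediumSpec) -> MultiCompartmentModel:
    """Open uptake for medium nutrients only.

    Exchange reactions are export-positive, so uptake is allowed by setting
    lb = -cap.  O₂ gets its own cap (20 by default); every other listed
    nutrient defaults to 100.  Amino-acid exchanges and non-medium
    exchanges stay closed for uptake (lb = 0).
    """
    out = model
    exchanges = {met_base_id(next(iter(r.stoichiometry))): r for r in out.exchange_reactions()}
    for nutrient in medium.nutrients:
        if nutrient not in exchanges:
            raise ModelIntegrityError(
                f"medium nutrient {nutrient!r} has no exchange reaction"
            )
    for base, rxn in exchanges.items():
        met = out.metabolites[next(iter(rxn.stoichiometry))]
        cap = medium.cap_for(base)
        if cap is not None and not (met.tags & medium.excluded_tags):
            rxn.lower_bound = -abs(cap)
        else:
            rxn.lower_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# host objective
# ---------------------------------------------------------------------------

@dataclass
class BiomassSpec:
    """Biomass component coefficients (mmol per gDW) with provenance."""

    components: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)  # amino_acid_composition | b_vitamin | structural

    def __post_init__(self) -> None:
        nonpos = [m for m, c in self.components.items() if c <= 0]
        if nonpos:
            raise ValueError(f"biomass coefficients must be positive: {nonpos}")


def build_objective(
    aa_mass_fractions: Dict[str, float],
    vitamins: Iterable[str] = (),
    vitamin_coeff: float = DEFAULT_VITAMIN_COEFF,
    protein_per_gdw: float = 1.0,
) -> BiomassSpec:
    """Host biomass composition from amino-acid mass fractions.

    coefficient_i = 1000 x fraction_i / MW_i x protein_per_gdw
    (mmol amino acid per gDW); each B vitamin is appended at
    ``vitamin_coeff``.
    """
    total = sum(aa_mass_fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"amino-acid mass fractions sum to {total}, expected 1")
    components: Dict[str, float] = {}
    provenance: Dict[str, str] = {}
    for aa, fraction in aa_mass_fractions.items():
        if aa not in AMINO_ACID_MW:
            raise ValueError(f"unknown amino acid {aa!r}")
        if fraction <= 0:
            continue
        components[aa] = 1000.0 * fraction / AMINO_ACID_MW[aa] * protein_per_gdw
        provenance[aa] = "amino_acid_composition"
    for vit in vitamins:
        components[vit] = vitamin_coeff
        provenance[vit] = "b_vitamin"
    return BiomassSpec(components, provenance)


def fix_symbiont_biomass(
    model: MultiCompartmentModel, floor: float = DEFAULT_BIOMASS_FLOOR
) -> MultiCompartmentModel:
    """Pin both symbiont biomass reactions to a growth floor (lb = floor)."""
    for comp in model.symbiont_compartments:
        rid = model.biomass_reactions.get(comp)
        if rid is None:
            raise ModelIntegrityError(
                f"no biomass reaction identified for symbiont compartment {comp!r}"
            )
        model.reactions[rid].lower_bound = floor
    return model
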