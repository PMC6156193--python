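"""Parameterized toy symbioses with analytically known optima.

The generator emits a miniature version of the system the pipeline targets:
a host compartment (``h``) that feeds two bacterial symbionts (``sA``
primary, ``sB`` coprimary) through cost-free transports, an external medium
(``e``) supplying glucose, ammonia and sulfate under aerobic caps, linear
essential-amino-acid (EAA) synthesis pathways partitioned between the
symbionts, ammonia overflow from the coprimary symbiont, an optional
cross-fed intermediate, and a host growth objective consuming every EAA
plus a B vitamin.

Every internal reaction is elementally balanced by construction (alphabet
C/H/N/O/S), which is what makes the nitrogen ledger close exactly.  The
designed pathway chemistry::

    0.5 glc + nh3 -> prec + h2o                (host, C3H7NO2 precursor)
    prec -> eaa_i                              (primary symbiont, isomerization)
    (1+f) prec -> eaa_j + f byprod + f nh3     (coprimary, overflow fraction f)
    prec -> xfd ; xfd -> eaa_B1                (optional cross-feed via host relay)
    prec -> bvit                               (coprimary B vitamin)
    b prec -> biomass                          (symbiont biomass, floored)

Because every pathway is a linear chain hanging off the objective, the FBA
optimum is the minimum over bottlenecks of capacity per unit objective
demand, and the generator computes it (plus the full exchange table,
nitrogen ledgers and maintenance costs) by closed-form arithmetic that
never touches the LP engine — the expectations are an independent oracle
for the solver stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .integration import (
    MediumSpec,
    MultiCompartmentModel,
    TransportEntry,
    apply_medium,
    build_multicompartment,
    fix_symbiont_biomass,
)
from .model_core import MetabolicModel, Metabolite, Reaction
from .model_io import ExpressionTable

__all__ = [
    "ToySymbiosisSpec",
    "ToySymbiosisBundle",
    "ToyExpectation",
    "DegenerateCase",
    "generate_toy_symbiosis",
    "generate_expression_table",
    "degenerate_case_suite",
]

FORMULAS = {
    "glc": "C6H12O6",
    "nh3": "H3N",
    "so4": "O4S",
    "o2": "O2",
    "h2o": "H2O",
    "prec": "C3H7NO2",
    "byprod": "C3H4O2",
    "xfd": "C3H7NO2",
    "bvit": "C3H7NO2",
}

TAGS = {
    "glc": {"central_carbon"},
    "so4": {"mineral"},
    "byprod": {"central_carbon"},
    "bvit": {"b_vitamin"},
}


@dataclass
class ToySymbiosisSpec:
    """Study conditions for one generated symbiosis.

    Defaults follow the biology being emulated: the primary symbiont covers
    7 EAAs and the coprimary the remaining 3; symbiont biomass is floored
    at 0.01 mmol gDW⁻¹ h⁻¹; the B vitamin enters the host objective at
    coefficient 5e-5; the coprimary wastes 30% extra precursor as ammonia
    overflow.  Glucose uptake (cap 10) is the designed bottleneck under the
    default capacity interval; randomness (fixed by ``seed``) affects only
    pathway capacities, never the topology.
    """

    n_eaa_primary: int = 7
    n_eaa_coprimary: int = 3
    capacity_interval: Tuple[float, float] = (2.5, 4.0)
    pathway_capacities: Optional[Dict[str, float]] = None
    cross_feed: Optional[Tuple[str, str, str]] = ("xfd", "sA", "sB")
    ammonia_overflow_rate: float = 0.3
    include_vitamin: bool = True
    vitamin_coeff: float = 5e-5
    biomass_coeff: float = 1.0
    floor_primary: float = 0.01
    floor_coprimary: float = 0.01
    glc_cap: float = 10.0
    nh3_cap: float = 100.0
    so4_cap: float = 100.0
    o2_cap: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eaa_primary < 1 or self.n_eaa_coprimary < 1:
            raise ValueError("each symbiont must synthesize at least one EAA")
        if not 0 <= self.ammonia_overflow_rate:
            raise ValueError("ammonia_overflow_rate must be nonnegative")
        if self.cross_feed is not None and self.cross_feed[1:] != ("sA", "sB"):
            raise ValueError("cross_feed route must be ('<met>', 'sA', 'sB')")


@dataclass
class ToyExpectation:
    """Closed-form ground truth, computed without the LP engine."""

    objective_value: float
    binding: str
    bottlenecks: Dict[str, float]
    #: flux expectations below are only stated when the optimum is uniquely
    #: determined (glucose strictly binding); otherwise None
    unique_fluxes: bool
    exchanges: Optional[Dict[str, Dict[str, Dict[str, float]]]]
    cross_feeds: List[Tuple[str, str, str, float]]
    eaa_total_release: Optional[float]
    eaa_shares: Optional[Dict[str, float]]
    ledgers: Optional[Dict[str, Dict[str, float]]]
    maintenance_costs: Optional[Dict[str, float]]


@dataclass
class ToySymbiosisBundle:
    """Generated models plus specs and the expectation oracle."""

    spec: ToySymbiosisSpec
    host: MetabolicModel
    symA: MetabolicModel
    symB: MetabolicModel
    transport_spec: List[TransportEntry]
    medium: MediumSpec
    eaa_names: List[str]
    expected: ToyExpectation

    def integrate(self) -> MultiCompartmentModel:
        """Merge, apply the medium and pin the biomass floors."""
        model = build_multicompartment(self.host, self.symA, self.symB, self.transport_spec)
        apply_medium(model, self.medium)
        fix_symbiont_biomass(model, self.spec.floor_primary)
        model.reactions[model.biomass_reactions["sB"]].lower_bound = self.spec.floor_coprimary
        return model


def _met(base: str, comp: str, extra_tags: Optional[set] = None) -> Metabolite:
    tags = set(TAGS.get(base, set()))
    if extra_tags:
        tags |= extra_tags
    # every EAA is a C3H7NO2 isomer of the precursor: balance by construction
    formula = FORMULAS.get(base, "C3H7NO2" if base.startswith("eaa") else "")
    return Metabolite(
        id=f"{base}[{comp}]",
        name=base,
        formula=formula,
        compartment_id=comp,
        tags=tags,
    )


def generate_toy_symbiosis(spec: ToySymbiosisSpec) -> ToySymbiosisBundle:
    """Build one toy symbiosis and its closed-form expectations."""
    rng = np.random.default_rng(spec.seed)
    f = spec.ammonia_overflow_rate
    x = 1 if spec.cross_feed is not None else 0
    v = spec.vitamin_coeff if spec.include_vitamin else 0.0
    b = spec.biomass_coeff
    n_a, n_b = spec.n_eaa_primary, spec.n_eaa_coprimary
    n_overflow = n_b - x  # coprimary pathways fed by precursor (with overflow)

    eaa_a = [f"eaaA{i + 1}" for i in range(n_a)]
    eaa_b = [f"eaaB{j + 1}" for j in range(n_b)]

    lo, hi = spec.capacity_interval
    caps: Dict[str, float] = {}
    for name in eaa_a + eaa_b + (["xfd"] if x else []):
        caps[name] = float(rng.uniform(lo, hi))
    if spec.pathway_capacities:
        caps.update(spec.pathway_capacities)
    if any(c <= 0 for c in caps.values()):
        raise ValueError("pathway capacities must be positive")

    # ---- host model -------------------------------------------------------
    host = MetabolicModel(id="toy_host")
    for base in ["glc", "nh3", "so4", "o2", "h2o", "prec", "byprod"]:
        host.add_metabolite(_met(base, "h"))
    for name in eaa_a + eaa_b:
        host.add_metabolite(_met(name, "h", {"eaa"}))
    if x:
        host.add_metabolite(_met("xfd", "h"))
    if spec.include_vitamin:
        host.add_metabolite(_met("bvit", "h"))
    host.add_reaction(
        Reaction(
            id="R_prec_syn",
            name="precursor synthesis",
            stoichiometry={"glc[h]": -0.5, "nh3[h]": -1.0, "prec[h]": 1.0, "h2o[h]": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            gene_association="gh1",
        )
    )
    biomass_stoich = {f"{name}[h]": -1.0 for name in eaa_a + eaa_b}
    if spec.include_vitamin:
        biomass_stoich["bvit[h]"] = -v
    host.add_reaction(
        Reaction(
            id="R_biomass_h",
            name="host growth",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="biomass",
        )
    )
    host.objective = {"R_biomass_h": 1.0}

    # ---- primary symbiont -------------------------------------------------
    symA = MetabolicModel(id="toy_symA")
    symA.add_metabolite(_met("prec", "sA"))
    for name in eaa_a:
        symA.add_metabolite(_met(name, "sA", {"eaa"}))
    if x:
        symA.add_metabolite(_met("xfd", "sA"))
    for i, name in enumerate(eaa_a):
        symA.add_reaction(
            Reaction(
                id=f"R_{name}_syn",
                name=f"{name} synthesis",
                stoichiometry={"prec[sA]": -1.0, f"{name}[sA]": 1.0},
                lower_bound=0.0,
                upper_bound=caps[name],
                gene_association=f"ga{i + 1}",
            )
        )
    if x:
        symA.add_reaction(
            Reaction(
                id="R_xfd_syn",
                name="cross-fed intermediate synthesis",
                stoichiometry={"prec[sA]": -1.0, "xfd[sA]": 1.0},
                lower_bound=0.0,
                upper_bound=caps["xfd"],
            )
        )
    symA.add_reaction(
        Reaction(
            id="R_biomass_sA",
            name="primary symbiont growth",
            stoichiometry={"prec[sA]": -b},
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="biomass",
        )
    )

    # ---- coprimary symbiont ----------------------------------------------
    symB = MetabolicModel(id="toy_symB")
    for base in ["prec", "nh3", "byprod"]:
        symB.add_metabolite(_met(base, "sB"))
    for name in eaa_b:
        symB.add_metabolite(_met(name, "sB", {"eaa"}))
    if x:
        symB.add_metabolite(_met("xfd", "sB"))
    if spec.include_vitamin:
        symB.add_metabolite(_met("bvit", "sB"))
    for j, name in enumerate(eaa_b):
        if x and j == 0:
            stoich = {"xfd[sB]": -1.0, f"{name}[sB]": 1.0}
        elif f > 0:
            stoich = {
                "prec[sB]": -(1.0 + f),
                f"{name}[sB]": 1.0,
                "byprod[sB]": f,
                "nh3[sB]": f,
            }
        else:
            stoich = {"prec[sB]": -1.0, f"{name}[sB]": 1.0}
        symB.add_reaction(
            Reaction(
                id=f"R_{name}_syn",
                name=f"{name} synthesis",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=caps[name],
                gene_association=f"gb{j + 1}",
            )
        )
    if spec.include_vitamin:
        symB.add_reaction(
            Reaction(
                id="R_bvit_syn",
                name="B vitamin synthesis",
                stoichiometry={"prec[sB]": -1.0, "bvit[sB]": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
    symB.add_reaction(
        Reaction(
            id="R_biomass_sB",
            name="coprimary symbiont growth",
            stoichiometry={"prec[sB]": -b},
            lower_bound=0.0,
            upper_bound=1000.0,
            kind="biomass",
        )
    )

    # ---- transports -------------------------------------------------------
    transports: List[TransportEntry] = [
        TransportEntry("glc", "e", "h", reversible=False),
        TransportEntry("nh3", "e", "h", reversible=False),
        TransportEntry("so4", "e", "h", reversible=False),
        TransportEntry("o2", "e", "h", reversible=False),
        TransportEntry("h2o", "h", "e", reversible=False),
        TransportEntry("byprod", "sB", "h", reversible=False),
        TransportEntry("byprod", "h", "e", reversible=False),
        TransportEntry("prec", "h", "sA", reversible=False),
        TransportEntry("prec", "h", "sB", reversible=False),
        TransportEntry("nh3", "sB", "h", reversible=False),
        # closed-for-uptake amino-acid exchange exercised by apply_medium
        TransportEntry(eaa_a[0], "h", "e", reversible=True),
    ]
    for name in eaa_a:
        transports.append(TransportEntry(name, "sA", "h", reversible=False))
    for name in eaa_b:
        transports.append(TransportEntry(name, "sB", "h", reversible=False))
    if x:
        transports.append(TransportEntry("xfd", "sA", "h", reversible=False))
        transports.append(TransportEntry("xfd", "h", "sB", reversible=False))
    if spec.include_vitamin:
        transports.append(TransportEntry("bvit", "sB", "h", reversible=False))

    medium = MediumSpec(
        uptake_caps={"glc": spec.glc_cap, "nh3": spec.nh3_cap, "so4": spec.so4_cap},
        o2_cap=spec.o2_cap,
    )

    expected = _closed_form_expectation(
        spec, caps, eaa_a, eaa_b, n_overflow, x, v, b, f
    )
    if expected.objective_value <= 0:
        raise ValueError(
            "spec is infeasible or degenerate: the biomass floors consume the "
            f"entire nutrient budget (closed-form optimum "
            f"{expected.objective_value:.4g} <= 0); lower the floors or raise "
            "the nutrient caps"
        )
    return ToySymbiosisBundle(
        spec=spec,
        host=host,
        symA=symA,
        symB=symB,
        transport_spec=transports,
        medium=medium,
        eaa_names=eaa_a + eaa_b,
        expected=expected,
    )


def _closed_form_expectation(
    spec: ToySymbiosisSpec,
    caps: Dict[str, float],
    eaa_a: Sequence[str],
    eaa_b: Sequence[str],
    n_overflow: int,
    x: int,
    v: float,
    b: float,
    f: float,
) -> ToyExpectation:
    """Bottleneck arithmetic for the designed topology (no LP involved)."""
    n_a, n_b = len(eaa_a), len(eaa_b)
    drain = b * (spec.floor_primary + spec.floor_coprimary)
    # precursor demand per unit host growth
    P = n_a + x + n_overflow * (1.0 + f) + v

    bottlenecks: Dict[str, float] = {}
    bottlenecks["glc"] = (2.0 * spec.glc_cap - drain) / P
    denom_n = P - f * n_overflow
    bottlenecks["nh3"] = (spec.nh3_cap - drain) / denom_n if denom_n > 0 else math.inf
    for name, cap in caps.items():
        bottlenecks[f"cap:{name}"] = cap
    binding = min(bottlenecks, key=bottlenecks.get)
    mu = bottlenecks[binding]

    ordered = sorted(bottlenecks.values())
    strict_glc = binding == "glc" and (
        len(ordered) < 2 or ordered[1] - ordered[0] > 1e-9 * max(1.0, ordered[0])
    )
    if not strict_glc:
        return ToyExpectation(
            objective_value=mu,
            binding=binding,
            bottlenecks=bottlenecks,
            unique_fluxes=False,
            exchanges=None,
            cross_feeds=[("xfd", "sA", "sB", mu)] if x else [],
            eaa_total_release=None,
            eaa_shares=None,
            ledgers=None,
            maintenance_costs=None,
        )

    prec_total = P * mu + drain
    prec_to_a = (n_a + x) * mu + b * spec.floor_primary
    prec_to_b = (n_overflow * (1.0 + f) + v) * mu + b * spec.floor_coprimary
    overflow = f * n_overflow * mu

    host_imports = {"glc": 0.5 * prec_total, "nh3": prec_total}
    for name in eaa_a + list(eaa_b):
        host_imports[name] = mu
    if v > 0:
        host_imports["bvit"] = v * mu
    host_exports = {"prec": prec_total, "h2o": prec_total}
    exchanges = {
        "h": {"imports": host_imports, "exports": host_exports},
        "sA": {
            "imports": {"prec": prec_to_a},
            "exports": {**{name: mu for name in eaa_a}, **({"xfd": mu} if x else {})},
        },
        "sB": {
            "imports": {"prec": prec_to_b, **({"xfd": mu} if x else {})},
            "exports": {
                **{name: mu for name in eaa_b},
                **({"nh3": overflow, "byprod": overflow} if overflow > 0 else {}),
                **({"bvit": v * mu} if v > 0 else {}),
            },
        },
    }

    n_in_a = prec_to_a  # every toy N carrier has one N atom except nothing here
    ledger_a = {
        "n_in": n_in_a,
        "n_out_eaa": n_a * mu,
        "n_out_other": x * mu,
        "n_biomass": b * spec.floor_primary,
    }
    n_in_b = prec_to_b + x * mu
    ledger_b = {
        "n_in": n_in_b,
        "n_out_eaa": n_b * mu,
        "n_out_other": overflow + v * mu,
        "n_biomass": b * spec.floor_coprimary,
    }
    for led in (ledger_a, ledger_b):
        led["efficiency"] = led["n_out_eaa"] / led["n_in"]

    maintenance = {
        "sA": b * spec.floor_primary / P,
        "sB": b * spec.floor_coprimary / P,
    }
    total_release = (n_a + n_b) * mu
    shares = {"sA": n_a / (n_a + n_b), "sB": n_b / (n_a + n_b)}
    return ToyExpectation(
        objective_value=mu,
        binding=binding,
        bottlenecks=bottlenecks,
        unique_fluxes=True,
        exchanges=exchanges,
        cross_feeds=[("xfd", "sA", "sB", mu)] if x else [],
        eaa_total_release=total_release,
        eaa_shares=shares,
        ledgers={"sA": ledger_a, "sB": ledger_b},
        maintenance_costs=maintenance,
    )


def generate_expression_table(
    n_genes: int,
    n_replicates: int = 2,
    zero_fraction: float = 0.0,
    seed: int = 0,
) -> ExpressionTable:
    """Log-normal TPM draws with a designated fraction of all-zero genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    tpm = rng.lognormal(mean=2.0, sigma=1.2, size=(n_genes, n_replicates))
    n_zero = int(zero_fraction * n_genes)
    if n_zero:
        zero_rows = rng.choice(n_genes, size=n_zero, replace=False)
        tpm[zero_rows, :] = 0.0
    df = pd.DataFrame(
        tpm, index=pd.Index(genes, name="gene_id"),
        columns=[f"rep{k + 1}" for k in range(n_replicates)],
    )
    return ExpressionTable(df)


@dataclass
class DegenerateCase:
    """A pathological fixture and the behavior the pipeline owes it."""

    name: str
    model: MetabolicModel
    expected: Dict[str, object]


def degenerate_case_suite() -> List[DegenerateCase]:
    """Edge-case fixtures: infeasibility, alternate optima, contract errors."""
    cases: List[DegenerateCase] = []

    # 1. blocked pathway with a demanded objective floor -> infeasible
    blocked = MetabolicModel(id="blocked")
    blocked.add_metabolite(Metabolite("A[c]", "A", "C1", "c"))
    blocked.add_metabolite(Metabolite("B[c]", "B", "C1", "c"))
    blocked.add_reaction(Reaction("U_A", stoichiometry={"A[c]": 1.0},
                                  lower_bound=0.0, upper_bound=5.0, kind="exchange"))
    blocked.add_reaction(Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                                  lower_bound=0.0, upper_bound=0.0))
    blocked.add_reaction(Reaction("D_B", stoichiometry={"B[c]": -1.0},
                                  lower_bound=0.01, upper_bound=1000.0, kind="exchange"))
    blocked.objective = {"D_B": 1.0}
    cases.append(DegenerateCase("blocked_infeasible", blocked,
                                {"status": "infeasible"}))

    # 2. two equivalent parallel routes sharing a capacity-5 uptake
    parallel = MetabolicModel(id="parallel_routes")
    parallel.add_metabolite(Metabolite("A[c]", "A", "C1", "c"))
    parallel.add_metabolite(Metabolite("B[c]", "B", "C1", "c"))
    parallel.add_reaction(Reaction("U_A", stoichiometry={"A[c]": 1.0},
                                   lower_bound=0.0, upper_bound=5.0, kind="exchange"))
    parallel.add_reaction(Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                                   lower_bound=0.0, upper_bound=1000.0))
    parallel.add_reaction(Reaction("R2", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                                   lower_bound=0.0, upper_bound=1000.0))
    parallel.add_reaction(Reaction("D_B", stoichiometry={"B[c]": -1.0},
                                   lower_bound=0.0, upper_bound=1000.0, kind="exchange"))
    parallel.objective = {"D_B": 1.0}
    cases.append(DegenerateCase(
        "parallel_routes", parallel,
        {"objective": 5.0, "ranges": {"R1": (0.0, 5.0), "R2": (0.0, 5.0)}},
    ))

    # 3. empty objective -> solve_fba must refuse
    zero_obj = MetabolicModel(id="zero_objective")
    zero_obj.add_metabolite(Metabolite("A[c]", "A", "C1", "c"))
    zero_obj.add_reaction(Reaction("U_A", stoichiometry={"A[c]": 1.0},
                                   lower_bound=0.0, upper_bound=5.0, kind="exchange"))
    zero_obj.add_reaction(Reaction("D_A", stoichiometry={"A[c]": -1.0},
                                   lower_bound=0.0, upper_bound=5.0, kind="exchange"))
    cases.append(DegenerateCase("zero_objective", zero_obj,
                                {"error": "ValueError"}))

    # 4. transported metabolite without a formula -> the ledger must error
    bundle = generate_toy_symbiosis(ToySymbiosisSpec(seed=4))
    model = bundle.integrate()
    for met in model.metabolites.values():
        if met.base_id == "prec":
            met.formula = ""
    cases.append(DegenerateCase("unformula_transport", model,
                                {"error": "FormulaError"}))
    return cases
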