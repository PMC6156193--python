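import numpy as np
import pandas as pd
import pytest

from symbioflux import (
    ExpressionTable,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    TransportEntry,
    apply_expression_bounds,
    apply_medium,
    build_multicompartment,
    build_objective,
    fix_symbiont_biomass,
    normalize_expression,
    solve_fba,
    solve_fva,
)
from symbioflux.integration import NormalizedExpression


def _table(d):
    return ExpressionTable(pd.DataFrame(d).set_index("gene_id"))


class TestNormalizeExpression:
    def test_worked_example(self):
        table = _table({"gene_id": ["g1", "g2", "g3"], "r1": [2.5, 5.0, 10.1]})
        assert normalize_expression(table).levels == {"g1": 1, "g2": 2, "g3": 4}

    def test_single_gene_self_normalizes(self):
        table = _table({"gene_id": ["g"], "r1": [37.2]})
        assert normalize_expression(table).levels == {"g": 1}

    def test_zero_tpm_substitution_per_replicate(self):
        """A zero-TPM gene inherits each replicate's lowest nonzero value."""
        table = _table({
            "gene_id": ["gz", "ga", "gb"],
            "r1": [0.0, 1.0, 4.0],
            "r2": [0.0, 2.0, 6.0],
        })
        levels = normalize_expression(table).levels
        # gz becomes (1.0, 2.0) -> mean 1.5 == ga's mean -> same level
        assert levels["gz"] == levels["ga"] == 1
        assert levels["gb"] == round(5.0 / 1.5)

    def test_half_up_rounding(self):
        table = _table({"gene_id": ["g1", "g2"], "r1": [2.0, 3.0]})
        # 3.0 / 2.0 = 1.5 rounds half-up to 2
        assert normalize_expression(table).levels == {"g1": 1, "g2": 2}

    def test_all_zero_errors(self):
        table = _table({"gene_id": ["g1"], "r1": [0.0]})
        with pytest.raises(ValueError, match="all zero"):
            normalize_expression(table)

    def test_minimum_level_is_one(self):
        from symbioflux import generate_expression_table

        for seed in range(25):
            table = generate_expression_table(40, 3, zero_fraction=0.15, seed=seed)
            levels = normalize_expression(table).levels
            assert min(levels.values()) == 1


def _gpr_model():
    m = MetabolicModel(id="gpr")
    m.add_metabolite(Metabolite("A[c]", formula="C1", compartment_id="c"))
    m.add_metabolite(Metabolite("B[c]", formula="C1", compartment_id="c"))
    m.add_reaction(Reaction("R_or", stoichiometry={"A[c]": -1, "B[c]": 1},
                            lower_bound=-1000, upper_bound=1000,
                            gene_association="g1 or g2"))
    m.add_reaction(Reaction("R_and", stoichiometry={"A[c]": -1, "B[c]": 1},
                            lower_bound=0, upper_bound=1000,
                            gene_association="g1 and g2"))
    m.add_reaction(Reaction("R_none", stoichiometry={"A[c]": -1, "B[c]": 1},
                            lower_bound=-1000, upper_bound=1000,
                            gene_association="gX"))
    m.add_reaction(Reaction("R_orphan", stoichiometry={"A[c]": -1, "B[c]": 1},
                            lower_bound=0, upper_bound=1000))
    return m


class TestExpressionBounds:
    def test_gpr_rules_and_defaults(self):
        expr = NormalizedExpression({"g1": 3, "g2": 5})
        out = apply_expression_bounds(_gpr_model(), expr)
        assert (out.reactions["R_or"].lower_bound,
                out.reactions["R_or"].upper_bound) == (-8, 8)
        assert (out.reactions["R_and"].lower_bound,
                out.reactions["R_and"].upper_bound) == (0, 3)
        # no transcript match -> default bound 10
        assert (out.reactions["R_none"].lower_bound,
                out.reactions["R_none"].upper_bound) == (-10, 10)
        assert (out.reactions["R_orphan"].lower_bound,
                out.reactions["R_orphan"].upper_bound) == (0, 10)

    def test_original_model_untouched(self):
        model = _gpr_model()
        apply_expression_bounds(model, NormalizedExpression({"g1": 2, "g2": 2}))
        assert model.reactions["R_or"].upper_bound == 1000


class TestBuildMulticompartment:
    def test_merge_keeps_all_reactions_with_provenance(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        n_sources = b.host.n_reactions + b.symA.n_reactions + b.symB.n_reactions
        n_transport = len(b.transport_spec)
        n_exchange = len(model.exchange_reactions())
        assert model.n_reactions == n_sources + n_transport + n_exchange
        roles = set(model.provenance.values())
        assert roles == {"host", "symA", "symB", "transport", "external"}

    def test_metabolite_bookkeeping(self, default_bundle):
        """Species duplicated across compartments are counted separately."""
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        externals = [m for m in model.metabolites.values() if m.compartment_id == "e"]
        assert model.n_metabolites == (
            b.host.n_metabolites + b.symA.n_metabolites + b.symB.n_metabolites
            + len(externals)
        )

    def test_transport_reaction_construction(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        rid = model.transport_registry[("prec", "h", "sA")]
        rxn = model.reactions[rid]
        assert rxn.stoichiometry == {"prec[h]": -1.0, "prec[sA]": 1.0}
        assert rxn.kind == "transport"
        assert rxn.is_one_to_one_transport()
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)

    def test_transports_carry_no_cost_metabolites(self, integrated_model):
        for rid in integrated_model.transport_reaction_ids():
            assert integrated_model.reactions[rid].is_one_to_one_transport()

    def test_missing_transport_endpoint_errors(self, default_bundle):
        b = default_bundle
        bad = list(b.transport_spec) + [TransportEntry("nonexistent", "h", "sA")]
        with pytest.raises(ModelIntegrityError, match="nonexistent"):
            build_multicompartment(b.host, b.symA, b.symB, bad)


class TestApplyMedium:
    def test_oxygen_and_default_caps(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        medium = MediumSpec(uptake_caps={"glc": None, "nh3": None, "so4": None})
        apply_medium(model, medium)
        assert model.reactions["EX_o2"].lower_bound == -20.0
        assert model.reactions["EX_glc"].lower_bound == -100.0

    def test_amino_acid_uptake_closed(self, integrated_model):
        eaa_exchange = integrated_model.reactions["EX_eaaA1"]
        assert eaa_exchange.lower_bound == 0.0

    def test_no_amino_acid_uptake_feasible(self, integrated_model):
        """FVA at the optimum never lets the EAA exchange run negative."""
        fva = solve_fva(integrated_model, reactions=["EX_eaaA1"])
        lo, hi = fva.ranges["EX_eaaA1"]
        assert lo >= -1e-9

    def test_missing_exchange_errors(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        with pytest.raises(ModelIntegrityError, match="unobtainium"):
            apply_medium(model, MediumSpec(uptake_caps={"unobtainium": 5.0}))


class TestBuildObjective:
    def test_vitamin_coefficient(self):
        spec = build_objective({"glycine": 1.0}, vitamins=["riboflavin"])
        assert spec.components["riboflavin"] == pytest.approx(5e-5)
        assert spec.provenance["riboflavin"] == "b_vitamin"

    def test_glycine_worked_example(self):
        spec = build_objective({"glycine": 0.075, "leucine": 0.925})
        assert spec.components["glycine"] == pytest.approx(0.999, abs=5e-4)

    def test_equal_fractions_equal_coefficients(self):
        spec = build_objective({"leucine": 0.5, "isoleucine": 0.5})
        assert spec.components["leucine"] == pytest.approx(spec.components["isoleucine"])

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            build_objective({"glycine": 0.4})

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="selenocysteine"):
            build_objective({"selenocysteine": 1.0})


class TestBiomassFloor:
    def test_floors_applied(self, integrated_model):
        for comp in integrated_model.symbiont_compartments:
            rid = integrated_model.biomass_reactions[comp]
            assert integrated_model.reactions[rid].lower_bound == pytest.approx(0.01)

    def test_floor_zero_relaxes(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        apply_medium(model, b.medium)
        fix_symbiont_biomass(model, floor=0.0)
        sol = solve_fba(model)
        assert sol.optimal
        for comp in model.symbiont_compartments:
            assert sol.flux[model.biomass_reactions[comp]] == pytest.approx(0.0, abs=1e-9)

    def test_floor_beyond_capacity_infeasible(self, default_bundle):
        b = default_bundle
        model = build_multicompartment(b.host, b.symA, b.symB, b.transport_spec)
        apply_medium(model, b.medium)
        fix_symbiont_biomass(model, floor=5000.0)
        assert solve_fba(model).status == "infeasible"
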