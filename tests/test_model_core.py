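import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symbioflux import (
    FormulaError,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    build_matrix,
    check_mass_balance,
    element_count,
    parse_formula,
)
from symbioflux.model_core import mass_balance_report, met_base_id, met_compartment


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("NH3", {"N": 1, "H": 3}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("C5H10N2O3", {"C": 5, "H": 10, "N": 2, "O": 3}),  # glutamine
        ("H2O", {"H": 2, "O": 1}),
        ("Fe", {"Fe": 1}),
        ("O4S", {"O": 4, "S": 1}),
    ],
)
def test_parse_formula_examples(formula, expected):
    assert parse_formula(formula) == expected


@pytest.mark.parametrize("bad", ["", "c6h12", "C6 H12", "6C", "C-3", "C3.5", "(CH2)3"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_parse_formula_error_names_position():
    with pytest.raises(FormulaError, match="position 2"):
        parse_formula("C6!H12")


_ELEMENTS = ["C", "H", "N", "O", "S", "P", "Fe", "Mg", "Na"]


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(st.sampled_from(_ELEMENTS), st.integers(1, 999)),
        min_size=1,
        max_size=6,
    )
)
def test_parse_formula_total_on_grammar(parts):
    """Any sequence of element+count tokens parses to the summed counts."""
    formula = "".join(f"{el}{n if n != 1 else ''}" for el, n in parts)
    counts = parse_formula(formula)
    expected = {}
    for el, n in parts:
        expected[el] = expected.get(el, 0) + n
    assert counts == expected


@settings(derandomize=True, max_examples=100)
@given(st.text(alphabet="abz09!# -[]", min_size=1, max_size=8))
def test_parse_formula_rejects_non_grammar(s):
    """Strings that cannot start with an element symbol are rejected."""
    with pytest.raises(FormulaError):
        parse_formula(s)


def test_element_count_and_missing_formula():
    gln = Metabolite("gln[h]", formula="C5H10N2O3")
    glc = Metabolite("glc[h]", formula="C6H12O6")
    nh3 = Metabolite("nh3[h]", formula="H3N")
    assert element_count(gln, "N") == 2
    assert element_count(glc, "N") == 0
    assert element_count(nh3, "N") == 1
    pseudo = Metabolite("biomass[h]", formula="")
    with pytest.raises(FormulaError, match="no formula"):
        element_count(pseudo, "N")


def test_compartment_suffix_helpers():
    assert met_base_id("gln[h]") == "gln"
    assert met_compartment("gln[h]") == "h"
    assert met_compartment("orphan") is None


def _two_met_model():
    m = MetabolicModel(id="tiny")
    m.add_metabolite(Metabolite("A[c]", formula="C1", compartment_id="c"))
    m.add_metabolite(Metabolite("B[c]", formula="C1", compartment_id="c"))
    return m


class TestBuildMatrix:
    def test_single_reaction_column(self):
        m = _two_met_model()
        m.add_reaction(Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0}))
        sm = build_matrix(m)
        assert sm.shape == (2, 1)
        np.testing.assert_array_equal(sm.toarray().ravel(), [-1.0, 1.0])

    def test_empty_model(self):
        sm = build_matrix(MetabolicModel(id="empty"))
        assert sm.shape == (0, 0)

    def test_round_trip_reconstruction(self, default_bundle):
        """Columns of S reproduce every reaction's stoichiometry exactly."""
        model = default_bundle.integrate()
        sm = build_matrix(model)
        for rid, rxn in model.reactions.items():
            assert sm.column(rid) == rxn.stoichiometry

    def test_dangling_reference_rejected(self):
        m = _two_met_model()
        with pytest.raises(ModelIntegrityError, match="ghost"):
            m.add_reaction(Reaction("R1", stoichiometry={"ghost[c]": -1.0}))


class TestMassBalance:
    def test_glutamine_synthesis_balances(self):
        m = MetabolicModel(id="gs")
        m.add_metabolite(Metabolite("glu[c]", formula="C5H9NO4", compartment_id="c"))
        m.add_metabolite(Metabolite("nh3[c]", formula="H3N", compartment_id="c"))
        m.add_metabolite(Metabolite("gln[c]", formula="C5H10N2O3", compartment_id="c"))
        m.add_metabolite(Metabolite("h2o[c]", formula="H2O", compartment_id="c"))
        rxn = Reaction(
            "GLNS",
            stoichiometry={"glu[c]": -1, "nh3[c]": -1, "gln[c]": 1, "h2o[c]": 1},
        )
        m.add_reaction(rxn)
        imbalance = check_mass_balance(rxn, m)
        assert imbalance is not None
        assert all(v == 0 for v in imbalance.values())

    def test_carbon_imbalance_detected(self):
        m = MetabolicModel(id="bad")
        m.add_metabolite(Metabolite("A[c]", formula="C1", compartment_id="c"))
        m.add_metabolite(Metabolite("B[c]", formula="C2", compartment_id="c"))
        rxn = Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0})
        m.add_reaction(rxn)
        assert check_mass_balance(rxn, m)["C"] == pytest.approx(1.0)

    def test_exchange_reported_unchecked(self):
        m = _two_met_model()
        rxn = Reaction("EX_A", stoichiometry={"A[c]": -1.0}, kind="exchange")
        m.add_reaction(rxn)
        assert check_mass_balance(rxn, m) is None

    def test_toy_internal_reactions_all_balanced(self, integrated_model):
        """Every generated internal/transport reaction balances C,H,N,O,S."""
        unbalanced, unchecked = mass_balance_report(integrated_model)
        assert unbalanced == []
        # only biomass/exchange-style reactions may be unchecked
        for rid in unchecked:
            assert integrated_model.reactions[rid].kind in {"biomass", "exchange"}


def test_model_counts_consistent(default_bundle):
    model = default_bundle.host
    assert model.n_reactions == len(model.reactions)
    assert model.n_metabolites == len(model.metabolites)
    assert model.n_genes == 1  # the single host gene association
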