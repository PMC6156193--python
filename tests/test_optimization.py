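import numpy as np
import pytest

from symbioflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    solve_fba,
    solve_fva,
    flux_range_summary,
    transport_flux_variation,
)
from symbioflux.optimization import FVAResult, FluxSolution, fraction_transports_below
from symbioflux.synthetic_data import degenerate_case_suite

from oracles import brute_force_lp, random_small_model


def _chain_model(cap=5.0, floor=0.0, blocked=False):
    """uptake(cap) -> A -> B -> drain, objective on the drain."""
    m = MetabolicModel(id="chain")
    m.add_metabolite(Metabolite("A[c]", formula="C1", compartment_id="c"))
    m.add_metabolite(Metabolite("B[c]", formula="C1", compartment_id="c"))
    m.add_reaction(Reaction("U", stoichiometry={"A[c]": 1.0},
                            lower_bound=0, upper_bound=cap, kind="exchange"))
    m.add_reaction(Reaction("R", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                            lower_bound=0, upper_bound=0.0 if blocked else 1000.0))
    m.add_reaction(Reaction("D", stoichiometry={"B[c]": -1.0},
                            lower_bound=floor, upper_bound=1000.0, kind="exchange"))
    m.objective = {"D": 1.0}
    return m


class TestSolveFBA:
    def test_single_bottleneck_chain(self):
        sol = solve_fba(_chain_model(cap=5.0))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0)
        assert sol.flux["R"] == pytest.approx(5.0)

    def test_blocked_chain_with_floor_infeasible(self):
        sol = solve_fba(_chain_model(floor=0.01, blocked=True))
        assert sol.status == "infeasible"
        assert np.isnan(sol.objective_value)

    def test_empty_objective_raises(self):
        m = _chain_model()
        m.objective = {}
        with pytest.raises(ValueError, match="empty objective"):
            solve_fba(m)

    def test_steady_state_and_bounds_respected(self, integrated_model):
        from symbioflux import build_matrix

        sol = solve_fba(integrated_model)
        sm = build_matrix(integrated_model)
        v = np.array([sol.flux[r] for r in sm.reaction_ids])
        assert np.max(np.abs(sm.matrix @ v)) <= 1e-9 * max(1.0, np.max(np.abs(v)))
        for rid, rxn in integrated_model.reactions.items():
            assert rxn.lower_bound - 1e-9 <= sol.flux[rid] <= rxn.upper_bound + 1e-9

    def test_deterministic_repeats(self, integrated_model):
        a = solve_fba(integrated_model)
        b = solve_fba(integrated_model)
        assert a.flux == b.flux

    def test_scaling_homogeneity(self, default_bundle):
        """Scaling every bound and cap by k scales the optimum by k."""
        base = solve_fba(default_bundle.integrate()).objective_value
        k = 3.0
        model = default_bundle.integrate()
        for rxn in model.reactions.values():
            rxn.lower_bound *= k
            rxn.upper_bound *= k
        scaled = solve_fba(model).objective_value
        assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_matches_brute_force_oracle_sample(self):
        rng = np.random.default_rng(20)
        for _ in range(15):
            model, S, lb, ub, c = random_small_model(rng)
            status, best = brute_force_lp(S, lb, ub, c)
            sol = solve_fba(model)
            assert sol.status == status
            if status == "optimal":
                assert sol.objective_value == pytest.approx(best, abs=1e-8)

    def test_cross_check_against_cobrapy(self, default_bundle, tmp_path):
        """Independent solver stack (cobrapy/GLPK) agrees on the optimum."""
        import cobra
        from symbioflux import write_sbml

        model = default_bundle.integrate()
        path = tmp_path / "integrated.xml"
        write_sbml(model, path)
        cmodel = cobra.io.read_sbml_model(str(path))
        expected = solve_fba(model).objective_value
        assert cmodel.slim_optimize() == pytest.approx(expected, rel=1e-6)


class TestSolveFVA:
    def test_uniquely_determined_chain(self):
        # ranges may widen by the objective-fixing slack (1e-6 x optimum)
        m = _chain_model(cap=5.0)
        sol = solve_fba(m)
        fva = solve_fva(m)
        for rid in m.reactions:
            lo, hi = fva.ranges[rid]
            assert lo == pytest.approx(hi, abs=2e-5)
            assert lo == pytest.approx(sol.flux[rid], abs=2e-5)

    def test_parallel_routes_full_range(self):
        case = next(c for c in degenerate_case_suite() if c.name == "parallel_routes")
        fva = solve_fva(case.model)
        for rid, (lo, hi) in case.expected["ranges"].items():
            got_lo, got_hi = fva.ranges[rid]
            assert got_lo == pytest.approx(lo, abs=1e-7)
            assert got_hi == pytest.approx(hi, abs=1e-7)

    def test_sandwich_property(self, integrated_model):
        sol = solve_fba(integrated_model)
        fva = solve_fva(integrated_model)
        for rid in integrated_model.reactions:
            lo, hi = fva.ranges[rid]
            assert lo - 1e-7 <= sol.flux[rid] <= hi + 1e-7
            assert lo <= hi + 1e-9

    def test_infeasible_model_raises(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            solve_fva(_chain_model(floor=0.01, blocked=True))

    def test_objective_fraction_widens_ranges(self, integrated_model):
        tight = solve_fva(integrated_model, reactions=["R_prec_syn"])
        loose = solve_fva(integrated_model, objective_fraction=0.5,
                          reactions=["R_prec_syn"])
        assert loose.range_width("R_prec_syn") >= tight.range_width("R_prec_syn") - 1e-9


class TestStabilizedMode:
    def test_preserves_optimum_and_shrinks_total_flux(self):
        case = next(c for c in degenerate_case_suite() if c.name == "parallel_routes")
        plain = solve_fba(case.model)
        stab = solve_fba(case.model, stabilize=True)
        assert stab.objective_value == pytest.approx(plain.objective_value, rel=1e-6)
        assert sum(map(abs, stab.flux.values())) <= sum(map(abs, plain.flux.values())) + 1e-6

    def test_deterministic_on_degenerate_model(self):
        case = next(c for c in degenerate_case_suite() if c.name == "parallel_routes")
        a = solve_fba(case.model, stabilize=True)
        b = solve_fba(case.model, stabilize=True)
        assert a.flux == b.flux


class TestSummaries:
    def test_all_zero_ranges_fraction_one(self):
        fva = FVAResult(ranges={"R1": (1.0, 1.0), "R2": (0.0, 0.0)}, objective_value=1.0)
        assert flux_range_summary(fva).fraction_below == 1.0

    def test_threshold_counts(self):
        fva = FVAResult(ranges={"R1": (0.0, 0.5), "R2": (0.0, 2.0)}, objective_value=1.0)
        assert flux_range_summary(fva, threshold=1.0).fraction_below == 0.5

    def test_transport_variation_arithmetic(self):
        fva = FVAResult(ranges={"T1": (1.0, 1.0), "T2": (0.995, 1.005), "T3": (0.0, 1.0)},
                        objective_value=1.0)
        sol = FluxSolution(status="optimal", objective_value=1.0,
                           flux={"T1": 1.0, "T2": 1.0, "T3": 0.0})
        var = transport_flux_variation(fva, sol, ["T1", "T2", "T3"])
        assert var["T1"] == pytest.approx(0.0)
        assert var["T2"] == pytest.approx(1.0)
        assert var["T3"] is None  # undefined at zero optimal flux
        assert fraction_transports_below(var, percent=0.5) == pytest.approx(0.5)

    def test_toy_bundle_fully_pinned(self, pipeline_result):
        """The glucose-limited toy has no alternative optima at all."""
        assert pipeline_result.range_summary.fraction_below == 1.0
        assert pipeline_result.transport_fraction_below == 1.0
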