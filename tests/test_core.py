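"""Stoichiometric core: model assembly, element audit, FBA and pFBA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_fba, random_toy_model
from syntroflux.core import (
    CompiledLP,
    Metabolite,
    ModelError,
    RatioConstraint,
    Reaction,
    build_model,
    check_element_balance,
    solve_fba,
    solve_fba_parsimonious,
)


class TestBuildModel:
    def test_minimal_chain_matrix(self, chain_model):
        assert chain_model.matrix.shape == (1, 2)
        assert chain_model.matrix.tolist() == [[1.0, -1.0]]

    def test_duplicate_ids_rejected(self):
        mets = [Metabolite("A"), Metabolite("A")]
        with pytest.raises(ModelError, match="duplicate"):
            build_model(mets, [Reaction("r", {"A": -1})], "r")

    def test_dangling_metabolite_rejected(self):
        with pytest.raises(ModelError, match="undeclared"):
            build_model(
                [Metabolite("A")], [Reaction("r", {"A": -1, "B": 1})], "r"
            )

    def test_missing_objective_rejected(self):
        with pytest.raises(ModelError, match="objective"):
            build_model([Metabolite("A")], [Reaction("r", {"A": -1})], "nope")

    def test_exchange_must_touch_one_external(self):
        mets = [Metabolite("A"), Metabolite("B")]
        with pytest.raises(ModelError, match="exchange"):
            build_model(
                mets,
                [Reaction("ex", {"A": -1, "B": 1}, is_exchange=True)],
                "ex",
            )


class TestElementBalance:
    def _toy(self, co2_coef):
        mets = [
            Metabolite("glc", formula={"C": 6, "H": 12, "O": 6}),
            Metabolite("pyr", formula={"C": 3, "H": 4, "O": 3}),
            Metabolite("co2", formula={"C": 1, "O": 2}),
            Metabolite("x", formula=None),
        ]
        rxns = [
            Reaction("split", {"glc": -1, "pyr": 2}),
            Reaction("bad", {"pyr": -1, "co2": co2_coef}),
            Reaction("mystery", {"x": -1}),
            Reaction("obj", {"pyr": -1}),
        ]
        return build_model(mets, rxns, "obj")

    def test_c6_splits_to_two_c3(self):
        report = check_element_balance(self._toy(co2_coef=3))
        assert "split" not in report.unbalanced

    def test_corrupted_co2_coefficient_detected(self):
        # pyruvate (C3) -> 4 CO2 is off by one carbon
        report = check_element_balance(self._toy(co2_coef=4))
        assert "bad" in report.unbalanced

    def test_missing_formula_reported_uncheckable(self):
        report = check_element_balance(self._toy(co2_coef=3))
        assert "mystery" in report.uncheckable
        assert "mystery" not in report.unbalanced


class TestFBA:
    def test_single_path_objective(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_steady_state_residual(self, chain_model):
        sol = solve_fba_parsimonious(chain_model)
        v = np.array([sol.fluxes[r] for r in chain_model.reaction_ids])
        assert np.max(np.abs(chain_model.matrix @ v)) <= 1e-9

    def test_unbounded_reported(self):
        # a growth reaction with no finite cap and a free internal cycle
        mets = [Metabolite("A")]
        rxns = [
            Reaction("make", {"A": 1}, 0, np.inf),
            Reaction("obj", {"A": -1}, 0, np.inf),
        ]
        model = build_model(mets, rxns, "obj")
        assert solve_fba(model).status == "unbounded"

    def test_infeasible_reported(self, chain_model):
        bad = RatioConstraint("uptake", "growth", 2.0)
        # uptake = 2*growth contradicts uptake = growth (mass balance)
        sol = solve_fba(chain_model, [bad])
        assert sol.status == "optimal" and sol.objective_value == pytest.approx(0.0, abs=1e-9)
        # truly inconsistent: force growth to a positive value
        mets = [Metabolite("A_ext", compartment="external"), Metabolite("A")]
        rxns = [
            Reaction("uptake", {"A_ext": -1, "A": 1}, 0, 10, is_exchange=True),
            Reaction("growth", {"A": -1}, 5, 1000),
        ]
        model = build_model(mets, rxns, "growth")
        sol = solve_fba(model, [RatioConstraint("uptake", "growth", 0.5)])
        assert sol.status == "infeasible"

    def test_ratio_constraint_enforced(self, diamond_symmetric):
        sol = solve_fba_parsimonious(
            diamond_symmetric, [RatioConstraint("p1", "p2", 3.0)]
        )
        assert sol.fluxes["p1"] == pytest.approx(3.0 * sol.fluxes["p2"], abs=1e-8)

    def test_relaxation_monotonicity(self, diamond_symmetric):
        constrained = solve_fba(
            diamond_symmetric, [RatioConstraint("p1", "p2", 1.0)]
        )
        relaxed = solve_fba(diamond_symmetric)
        assert relaxed.objective_value >= constrained.objective_value - 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=0.05, max_value=20.0))
    def test_scaling_homogeneity(self, k):
        """Scaling all bounds by k > 0 scales the optimum by k."""
        mets = [
            Metabolite("A_ext", compartment="external"),
            Metabolite("A"),
            Metabolite("B"),
        ]

        def _make(scale):
            rxns = [
                Reaction("up", {"A_ext": -1, "A": 1}, 0, 10 * scale, is_exchange=True),
                Reaction("p1", {"A": -1, "B": 1}, 0, 4 * scale),
                Reaction("p2", {"A": -1, "B": 1}, 0, 7 * scale),
                Reaction("growth", {"B": -1}, 0, 1000 * scale),
            ]
            return build_model(mets, rxns, "growth")

        base = solve_fba(_make(1.0)).objective_value
        scaled = solve_fba(_make(k)).objective_value
        assert scaled == pytest.approx(k * base, rel=1e-9)


class TestParsimonious:
    def test_unequal_paths_use_the_shorter(self, diamond_asymmetric):
        """The L1-minimal optimum routes everything through the one-step
        branch; an all-through-the-long-path vertex is never returned."""
        sol = solve_fba_parsimonious(diamond_asymmetric)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.fluxes["p2a"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["p1"] == pytest.approx(10.0, abs=1e-9)

    def test_single_path_matches_plain_fba(self, chain_model):
        plain = solve_fba(chain_model)
        pars = solve_fba_parsimonious(chain_model)
        for r in chain_model.reaction_ids:
            assert pars.fluxes[r] == pytest.approx(plain.fluxes[r], abs=1e-9)

    def test_repeated_calls_bitwise_identical(self, diamond_symmetric):
        a = solve_fba_parsimonious(diamond_symmetric)
        b = solve_fba_parsimonious(diamond_symmetric)
        assert a.fluxes == b.fluxes


class TestOracleEquivalence:
    def test_fba_matches_vertex_enumeration(self, rng):
        """On tiny random networks, HiGHS agrees with brute-force vertex
        enumeration of the feasible polytope to 1e-9."""
        checked = 0
        for _ in range(25):
            model = random_toy_model(rng)
            best, _opt = brute_force_fba(model)
            sol = solve_fba(model)
            assert sol.status == "optimal"
            assert sol.objective_value == pytest.approx(best, abs=1e-9)
            checked += 1
        assert checked == 25

    def test_parsimonious_flux_is_a_feasible_optimum(self, rng):
        for _ in range(10):
            model = random_toy_model(rng)
            best, _ = brute_force_fba(model)
            sol = solve_fba_parsimonious(model)
            v = np.array([sol.fluxes[r] for r in model.reaction_ids])
            assert np.max(np.abs(model.matrix @ v)) <= 1e-7
            lb, ub = model.bounds_arrays()
            assert np.all(v >= lb - 1e-8) and np.all(v <= ub + 1e-8)
            assert sol.objective_value == pytest.approx(best, abs=1e-8)


class TestCompiledLP:
    def test_minmax_flux_brackets_parsimonious(self, diamond_symmetric):
        lp = CompiledLP(diamond_symmetric)
        sol = lp.solve()
        lb = lp.lb.copy()
        lb[lp.obj_idx] = sol.objective_value - 1e-9
        lo, hi = lp.minmax_flux("p1", lb, lp.ub)
        assert lo - 1e-9 <= sol.fluxes["p1"] <= hi + 1e-9
        assert (lo, hi) == (pytest.approx(0.0, abs=1e-8), pytest.approx(10.0, abs=1e-8))
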