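"""Dynamic layer: uptake kinetics, integration, conservation, coupling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syntroflux import config
from syntroflux.community import BIOMASS_CARBON_MMOL_PER_GDW
from syntroflux.core import solve_fba
from syntroflux.dfba import (
    CommunityState,
    SimulationConfig,
    UptakeKinetics,
    community_rhs,
    interaction_yields,
    simulate_batch,
    uptake_rate,
)


class TestUptakeRate:
    @pytest.mark.parametrize(
        "S, expected_factor",
        [(0.0, 0.0), (0.5, 0.5), (4.5, 0.9)],  # S=Km -> 1/2, S=9Km -> 0.9
    )
    def test_closed_forms(self, S, expected_factor):
        kin = UptakeKinetics("up", vmax=8.0, km=0.5)
        assert uptake_rate(kin, S) == pytest.approx(8.0 * expected_factor)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            uptake_rate(UptakeKinetics("up", 1.0, 1.0), -0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(S=st.floats(min_value=0.0, max_value=1e4))
    def test_bounded_and_monotone(self, S):
        kin = UptakeKinetics("up", vmax=5.0, km=0.2)
        v = uptake_rate(kin, S)
        assert 0.0 <= v <= 5.0
        assert uptake_rate(kin, S + 1.0) >= v

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            UptakeKinetics("up", vmax=-1.0, km=1.0)
        with pytest.raises(ValueError):
            UptakeKinetics("up", vmax=1.0, km=0.0)


class TestRHS:
    def test_empty_culture_has_zero_derivatives(self):
        cond = config.condition("NH4_NO3")
        com = config.build_community(cond)
        state = CommunityState(
            0.0,
            {sp.species_name: 0.0 for sp in com.species},
            dict(cond.initial_state.concentration),
        )
        dX, dS, mu, _ = community_rhs(state, com, SimulationConfig())
        assert all(v == 0.0 for v in dX.values())
        assert all(v == 0.0 for v in dS.values())
        assert all(v == 0.0 for v in mu.values())

    def test_saturating_monoculture_growth_rate(self):
        """At S >> Km the growth rate equals the FBA objective with the
        uptake bounded at Vmax."""
        cond = config.condition("NH4")
        com = config.build_community(cond, species=("clostridium",))
        state = CommunityState(
            0.0, {"clostridium": 0.01},
            {**cond.initial_state.concentration, "glc_e": 5000.0, "nh4_e": 5000.0},
        )
        _, _, mu, _ = community_rhs(state, com, SimulationConfig())
        # independent check: cap uptake at Vmax in a static FBA
        sp = com.species[0]
        model = sp.model
        vmax = cond.parameters["clostridium.glucose_vmax"]
        from syntroflux.core import CompiledLP

        lp = CompiledLP(model, sp.ratio_constraints)
        ub = lp.ub.copy()
        ub[model._rxn_index["EX_glc"]] = vmax
        ref = lp.solve(lp.lb, ub)
        assert mu["clostridium"] == pytest.approx(
            ref.objective_value, rel=1e-3
        )


class TestBatchIntegration:
    def test_exponential_growth_closed_form(self):
        """Saturating-substrate monoculture follows X0*exp(mu_max*t) to
        within 0.1% at dt = 0.001 h (explicit Euler error bound)."""
        cond = config.condition("NH4")
        com = config.build_community(cond, species=("clostridium",))
        initial = CommunityState(
            0.0, {"clostridium": 0.01},
            {**cond.initial_state.concentration, "glc_e": 2000.0, "nh4_e": 500.0},
        )
        tc = simulate_batch(
            com, initial, SimulationConfig(t_end=2.0, dt=0.001)
        )
        mu0 = tc.growth_rate["clostridium"][0]
        expected = 0.01 * np.exp(mu0 * tc.times[-1])
        rel_err = abs(tc.biomass["clostridium"][-1] - expected) / expected
        assert rel_err < 1e-3

    def test_determinism_bitwise(self):
        cond = config.condition("NH4")
        com = config.build_community(cond, species=("clostridium",))
        cfg = SimulationConfig(t_end=2.0, dt=0.05)
        a = simulate_batch(com, cond.initial_state, cfg)
        b = simulate_batch(com, cond.initial_state, cfg)
        assert np.array_equal(
            a.biomass["clostridium"], b.biomass["clostridium"]
        )
        assert all(
            np.array_equal(a.concentration[m], b.concentration[m])
            for m in a.concentration
        )

    def test_step_halving_convergence(self):
        cond = config.condition("NH4")
        com = config.build_community(cond, species=("clostridium",))
        ends = {}
        for dt in (0.02, 0.01):
            tc = simulate_batch(
                com, cond.initial_state, SimulationConfig(t_end=10.0, dt=dt)
            )
            ends[dt] = tc.biomass["clostridium"][-1]
        assert abs(ends[0.01] - ends[0.02]) / ends[0.01] < 5e-3

    def test_glucose_vmax_monotonicity(self):
        """Raising the glucose Vmax weakly increases fermenter biomass at
        every time point."""
        tcs = {}
        for vmax in (4.0, 5.5):
            cond = config.condition(
                "NH4", params={"clostridium.glucose_vmax": vmax}
            )
            com = config.build_community(cond, species=("clostridium",))
            tcs[vmax] = simulate_batch(
                com, cond.initial_state, SimulationConfig(t_end=8.0, dt=0.02)
            )
        lo = tcs[4.0].biomass["clostridium"]
        hi = tcs[5.5].biomass["clostridium"]
        assert np.all(hi >= lo - 1e-12)

    def test_non_negative_state(self, batches):
        for name in config.CONDITIONS:
            _, _, tc = batches.get(name)
            for arr in tc.concentration.values():
                assert arr.min() >= -1e-12
            for arr in tc.biomass.values():
                assert arr.min() >= 0.0

    def test_wolinella_growth_stops_when_no3_exhausted(self):
        """The respirer's growth rate collapses to zero from the moment
        nitrate runs out."""
        cond = config.condition("NO3", params={
            "init.x0_clostridium": 0.0, "init.x0_wolinella": 0.05,
        })
        initial = cond.initial_state
        initial.concentration.update(
            {"h2_e": 10.0, "ac_e": 3.0, "no3_e": 0.3, "no2_e": 0.2}
        )
        com = config.build_community(cond, species=("wolinella",))
        tc = simulate_batch(com, initial, SimulationConfig(t_end=10.0, dt=0.02))
        mu = tc.growth_rate["wolinella"]
        no3 = tc.concentration["no3_e"]
        assert mu[0] > 0.05
        exhausted = no3 < 1e-9
        assert exhausted.any()
        k0 = int(np.argmax(exhausted))
        assert np.all(mu[k0 + 1:] <= 1e-9)


class TestConservationAndCoupling:
    @staticmethod
    def _total_carbon(tc, k):
        c = tc.concentration
        mmol_c = (
            6 * c["glc_e"][k] + 2 * c["ac_e"][k] + 4 * c["but_e"][k]
            + c["co2_e"][k] + c.get("for_e", np.zeros_like(tc.times))[k]
        )
        for sp in tc.species:
            mmol_c += BIOMASS_CARBON_MMOL_PER_GDW * tc.biomass[sp][k]
        return mmol_c

    @pytest.mark.parametrize("name", ["NH4_NO3", "NH4", "NO3", "N2"])
    def test_carbon_conserved(self, batches, name):
        _, _, tc = batches.get(name)
        c0 = self._total_carbon(tc, 0)
        cT = self._total_carbon(tc, -1)
        assert abs(cT - c0) / c0 <= 1e-3

    def test_electron_identity_every_step(self, batches):
        """Ferredoxin bookkeeping holds at every stored step: electrons in
        (PFOR + transhydrogenase) equal electrons out (hydrogenase + 3x
        nitrite reductase + 4x nitrogenase)."""
        for name in ("NH4_NO3", "N2"):
            _, _, tc = batches.get(name)
            f = tc.fluxes["clostridium"]
            resid = f["PFOR"] + f["FNOR"] - f["HYD"] - 3 * f["NIR"] - 4 * f["NIF"]
            # exact up to the LP solver tolerance (fluxes are O(1-5))
            assert np.max(np.abs(resid)) <= 1e-7

    def test_yield_constancy_along_trajectory(self, batches):
        """Specific rates scale linearly with the growth rate: regressing
        glucose uptake (and H2 export) on mu gives R^2 > 0.999."""
        _, _, tc = batches.get("NH4_NO3")
        mu = tc.growth_rate["clostridium"]
        mask = mu > 0.01
        for rxn in ("EX_glc", "EX_h2", "EX_ac"):
            v = tc.fluxes["clostridium"][rxn][mask]
            x = mu[mask]
            slope = np.dot(x, v) / np.dot(x, x)  # line through origin
            ss_res = np.sum((v - slope * x) ** 2)
            ss_tot = np.sum((v - v.mean()) ** 2)
            assert 1 - ss_res / ss_tot > 0.999

    def test_growth_coupling_in_no3_condition(self, batches):
        """Balanced growth: after the transient the two species' specific
        growth rates agree within 1% while glucose still drives growth."""
        _, _, tc = batches.get("NO3")
        mu_ca = tc.growth_rate["clostridium"]
        mu_ws = tc.growth_rate["wolinella"]
        window = (tc.times >= 10.0) & (tc.concentration["glc_e"] > 0.3)
        assert window.sum() > 100
        gap = np.abs(mu_ca[window] - mu_ws[window]) / mu_ca[window]
        assert gap.max() < 0.01

    @pytest.mark.parametrize("name", ["NH4", "N2"])
    def test_wolinella_dormant_without_nitrate(self, batches, name):
        _, _, tc = batches.get(name)
        assert tc.growth_rate["wolinella"].max() == 0.0
        assert tc.biomass["wolinella"][-1] == tc.biomass["wolinella"][0]

    def test_h2_accumulates_only_without_nitrate(self, batches):
        h2_end = {
            name: batches.get(name)[2].concentration["h2_e"][-1]
            for name in config.CONDITIONS
        }
        assert h2_end["NH4"] > 1.0 and h2_end["N2"] > 0.5
        assert h2_end["NH4_NO3"] < 0.05 and h2_end["NO3"] < 0.05


class TestYields:
    def test_forced_all_acetate_matches_hand_electron_balance(self):
        """Monoculture with the butyrate/acetate ratio pinned at zero:
        H2 per glucose equals the closed-form value
        4 - (c_pyr + c_nadh) * 4 / (c_atp + c_pyr) from the surrogate's
        electron and ATP balances."""
        from syntroflux.community import CLOSTRIDIUM_BIOMASS as B

        cond = config.condition("NH4", params={"ratio.butyrate_acetate": 0.0})
        com = config.build_community(cond, species=("clostridium",))
        tc = simulate_batch(
            com, cond.initial_state, SimulationConfig(t_end=12.0, dt=0.02)
        )
        y = interaction_yields(tc, com)["clostridium"]
        expected = 4.0 - (B["pyruvate"] + B["nadh"]) * 4.0 / (
            B["atp"] + B["pyruvate"]
        )
        assert y["h2_e"] == pytest.approx(expected, rel=1e-3)
        assert y["but_e"] == pytest.approx(0.0, abs=1e-9)

    def test_yields_error_when_nothing_consumed(self):
        cond = config.condition("NH4")
        com = config.build_community(cond, species=("clostridium",))
        initial = cond.initial_state
        initial.concentration["glc_e"] = 0.0
        tc = simulate_batch(com, initial, SimulationConfig(t_end=0.5, dt=0.05))
        with pytest.raises(ValueError, match="reference"):
            interaction_yields(tc, com)
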