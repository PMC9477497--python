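"""Root-shoot DEB model: flux cascade bookkeeping and emergent dynamics."""

import dataclasses

import numpy as np
import pytest

from plantdeb.environment import make_scenario
from plantdeb.root_shoot import (
    STATE_NAMES,
    PlantParams,
    PlantState,
    acquisition,
    assemble_reserves,
    derivatives,
    flux_ledger,
    ledger_closure,
    maintenance_and_growth,
    mass_balance_audit,
    mobilization,
    senesce_and_resorb,
    simulate,
    starvation_check,
    translocate,
)
from plantdeb.sim_engine import SolverSettings


class TestParamsValidation:
    def test_defaults_valid(self):
        PlantParams()

    def test_stoichiometric_closure_enforced(self):
        with pytest.raises(ValueError, match="closure"):
            PlantParams(y_EN_V=0.1, n_NE=0.25, n_NV=0.05)  # 0.025 < 0.05

    def test_translocation_efficiency_range(self):
        with pytest.raises(ValueError, match="eta_T"):
            PlantParams(eta_T=1.5)
        with pytest.raises(ValueError, match="eta_T"):
            PlantParams(eta_T=0.0)

    def test_errors_are_aggregated(self):
        with pytest.raises(ValueError) as err:
            PlantParams(eta_T=2.0, sigma=-0.5)
        assert "eta_T" in str(err.value) and "sigma" in str(err.value)


class TestAcquisition:
    def test_no_structure_no_acquisition(self, plant_params, balanced_env):
        state = PlantState(M_V_S=0.0)
        J_C, _ = acquisition(state, balanced_env.at(0.0), plant_params)
        assert J_C == 0.0

    def test_v1_morph_linearity(self, plant_params, balanced_env):
        env = balanced_env.at(0.0)
        J1, _ = acquisition(PlantState(M_V_S=1.0), env, plant_params)
        J2, _ = acquisition(PlantState(M_V_S=2.0), env, plant_params)
        assert J2 == pytest.approx(2.0 * J1)

    def test_half_saturation_composition(self, plant_params):
        """All channels at half-saturation, j_CAm=1, M_V_S=2 -> J_A_C = 0.5."""
        env = dict(co2=1.0, light=1.0, soil_n=1.0, temperature=plant_params.T_ref)
        state = PlantState(M_V_S=2.0)
        J_C, _ = acquisition(state, env, plant_params)
        assert J_C == pytest.approx(2.0 * 1.0 * 0.5 * 0.5)

    def test_pcsu_light_mode_is_less_than_minimum_of_factors(self):
        params = PlantParams(light_mode="pcsu")
        env = dict(co2=1.0, light=1.0, soil_n=1.0, temperature=params.T_ref)
        J_C, _ = acquisition(PlantState(M_V_S=1.0), env, params)
        assert J_C == pytest.approx(2.0 / 3.0 * 0.5)  # PCSU of two half-saturated factors


class TestMobilization:
    def test_empty_reserve_no_flux(self, plant_params):
        state = PlantState(m_EC_S=0.0)
        assert mobilization(state, plant_params)["mob_EC_S"] == 0.0

    def test_first_order_arithmetic(self):
        params = PlantParams(nu_EC=0.5)
        state = PlantState(m_EC_S=0.2, M_V_S=10.0)
        assert mobilization(state, params)["mob_EC_S"] == pytest.approx(1.0)


class TestMaintenanceAndGrowth:
    def test_maintenance_exactly_consumes_c_flux(self, plant_params):
        """Catabolic C flux equal to the maintenance demand: zero growth,
        zero deficit, the whole N-reserve flux is surplus."""
        out = maintenance_and_growth(0.5, 0.3, 0.5, 0.2, plant_params)
        assert out["growth_syn"] == 0.0
        assert out["maint_deficit"] == 0.0
        assert out["surplus_EN"] == pytest.approx(0.3)

    def test_starvation_limit_reports_full_deficit(self, plant_params):
        out = maintenance_and_growth(0.0, 0.0, 0.7, 0.2, plant_params)
        assert out["maint_deficit"] == pytest.approx(0.7)

    def test_balanced_growth_su_yields_two_thirds_and_product_split(self):
        """Post-maintenance scaled arrivals equal: synthesis is 2/3 of the
        minimum-rule reference; kappa_P diverts its fraction to products."""
        params = PlantParams(kappa_P_S=0.2)
        J_EC, J_EN = params.y_EC_V * 1.0, params.y_EN_V * 1.0  # rho = (1, 1)
        out = maintenance_and_growth(J_EC, J_EN, 0.0, 0.2, params)
        assert out["growth_syn"] == pytest.approx(2.0 / 3.0)
        assert out["growth_struct"] == pytest.approx(0.8 * 2.0 / 3.0)
        assert out["growth_prod"] == pytest.approx(0.2 * 2.0 / 3.0)


class TestTranslocate:
    def test_lossless_transfer(self):
        params = PlantParams(eta_T=1.0)
        out = translocate(1.0, 0.5, 0.25, 0.125, params)
        total_in = 1.0 + 0.5 + 0.25 + 0.125
        total_delivered = (
            out["transloc_EC_StoR"] + out["transloc_EN_StoR"]
            + out["transloc_EC_RtoS"] + out["transloc_EN_RtoS"]
        )
        assert total_delivered == pytest.approx(total_in)
        assert out["transloc_loss_C"] == 0.0

    def test_dissipative_transfer(self):
        params = PlantParams(eta_T=0.9)
        out = translocate(1.0, 0.0, 0.0, 0.0, params)
        assert out["transloc_EC_StoR"] == pytest.approx(0.9)
        assert out["transloc_loss_C"] == pytest.approx(0.1)


class TestAssembleReserves:
    def test_zero_nitrogen_routes_all_carbon_to_c_reserves(self, plant_params):
        out = assemble_reserves(1.0, 0.0, 0.5, plant_params)
        assert out["asm_S_syn"] == 0.0
        assert out["asm_R_syn"] == 0.0
        assert out["asm_S_rej_C"] == pytest.approx(1.0)
        assert out["asm_R_rej_C"] == pytest.approx(0.5)

    def test_full_xylem_routing(self):
        """lambda_N = 1 with no shoot-derived CH2O at the root: all uptake N
        reaches the shoot assembly SU, root N-reserve synthesis is zero."""
        params = PlantParams(lambda_N=1.0)
        out = assemble_reserves(1.0, 0.4, 0.0, params)
        assert out["asm_R_syn"] == 0.0
        assert out["asm_S_in_N"] == pytest.approx(0.4)

    def test_priority_of_n_reserve_formation(self, plant_params):
        """The N-reserve SU sees raw photosynthate; the C reserve only ever
        receives its rejection."""
        out = assemble_reserves(2.0, 0.3, 0.0, plant_params)
        consumed = plant_params.y_C_EN * out["asm_S_syn"]
        assert out["asm_S_rej_C"] == pytest.approx(2.0 - consumed)
        assert out["asm_S_syn"] > 0.0


class TestSenescence:
    def test_no_turnover_no_litter(self):
        params = PlantParams(h_V=0.0)
        out = senesce_and_resorb(PlantState(M_V_S=10.0), params)
        assert out["litter_struct_C"] == 0.0
        assert out["sen_loss_S"] == 0.0

    def test_full_resorption_leaves_no_structural_litter(self):
        params = PlantParams(sigma=1.0)
        out = senesce_and_resorb(PlantState(M_V_S=10.0, M_V_R=5.0), params)
        assert out["litter_struct_C"] == 0.0
        assert out["litter_struct_N"] == 0.0
        # resorbed C and N-reserve inflows account for the entire loss
        loss = out["sen_loss_S"]
        assert out["resorb_EC_S"] + out["resorb_EN_S"] == pytest.approx(loss)

    def test_half_resorption_arithmetic(self):
        params = PlantParams(h_V=0.01, sigma=0.5)
        out = senesce_and_resorb(PlantState(M_V_S=100.0), params)
        assert out["sen_loss_S"] == pytest.approx(1.0)
        assert out["resorb_EC_S"] + out["resorb_EN_S"] == pytest.approx(0.5)
        assert out["litter_struct_C"] == pytest.approx(
            0.5 + (1.0 - params.sigma) * params.h_V * PlantState().M_V_R
        )


class TestDerivatives:
    def test_all_zero_state_is_absorbing(self, plant_params, balanced_env):
        state = PlantState(**{n: 0.0 for n in STATE_NAMES})
        dydt, _ = derivatives(0.0, state, balanced_env, plant_params)
        assert np.all(dydt == 0.0)

    def test_dead_plant_has_zero_derivatives(self, plant_params, balanced_env):
        state = PlantState(alive=False)
        dydt, ledger = derivatives(0.0, state, balanced_env, plant_params)
        assert np.all(dydt == 0.0) and ledger == {}

    def test_internal_subsystem_is_organ_symmetric(self, zero_env):
        """With no assimilation, identical organ parameters and mirrored
        state, the shoot and root derivative blocks are mirror images."""
        params = PlantParams(kappa_P_S=0.15, kappa_P_R=0.15)
        state = PlantState(
            M_V_S=2.0, M_V_R=2.0, m_EC_S=0.4, m_EN_S=0.2, m_EC_R=0.4, m_EN_R=0.2
        )
        dydt, _ = derivatives(0.0, state, zero_env, params)
        d = dict(zip(STATE_NAMES, dydt))
        assert d["M_V_S"] == pytest.approx(d["M_V_R"], rel=1e-12)
        assert d["m_EC_S"] == pytest.approx(d["m_EC_R"], rel=1e-12)
        assert d["m_EN_S"] == pytest.approx(d["m_EN_R"], rel=1e-12)

    def test_ledger_elemental_closure_at_random_states(self, plant_params, balanced_env, rng):
        """Signed C and N sums of the ledger vanish for arbitrary states."""
        for _ in range(100):
            y = rng.uniform(0.0, 5.0, size=len(STATE_NAMES))
            state = PlantState.from_vector(y)
            ledger = flux_ledger(3.0, state, balanced_env, plant_params)
            resid_C, resid_N = ledger_closure(ledger, plant_params)
            assert abs(resid_C) < 1e-12 * max(1.0, ledger["J_A_C"])
            assert abs(resid_N) < 1e-12 * max(1.0, ledger["J_A_N"])

    def test_closure_holds_with_shrinkage_enabled(self, zero_env):
        params = PlantParams(allow_shrinkage=True)
        state = PlantState(m_EC_S=0.01, m_EN_S=0.01, m_EC_R=0.01, m_EN_R=0.01)
        ledger = flux_ledger(0.0, state, zero_env, params)
        assert ledger["shrink_S"] > 0.0
        resid_C, resid_N = ledger_closure(ledger, params)
        assert abs(resid_C) < 1e-12 and abs(resid_N) < 1e-12


class TestAudit:
    def test_corrupted_ledger_is_detected(self, plant_params, balanced_env):
        """Fault injection: doubling one recorded flux breaks the audit."""
        traj = simulate(
            PlantState(), balanced_env, plant_params,
            SolverSettings(t_span=(0.0, 20.0), record_every=1.0),
        )
        clean_C, clean_N = mass_balance_audit(traj, plant_params)
        assert max(clean_C, clean_N) < 1e-6
        traj.ledgers.loc[5, "growth_co2_S"] *= 2.0
        bad_C, _ = mass_balance_audit(traj, plant_params)
        assert bad_C > 1e-6

    def test_short_run_closure_at_integrator_tolerance(self, plant_params, balanced_env):
        traj = simulate(
            PlantState(), balanced_env, plant_params,
            SolverSettings(t_span=(0.0, 100.0), record_every=1.0),
        )
        err_C, err_N = mass_balance_audit(traj, plant_params)
        assert err_C < 1e-8 and err_N < 1e-8


class TestStarvation:
    def test_abundant_reserves_alive(self, plant_params, balanced_env):
        state = PlantState()
        ledger = flux_ledger(0.0, state, balanced_env, plant_params)
        alive, event = starvation_check(state, ledger, plant_params)
        assert alive and event is None

    def test_deficit_with_full_partner_reserves_still_kills(self, plant_params, zero_env):
        """Shoot deficit with empty shoot reserves is lethal even when root
        reserves are full (no structure-shrinkage rescue by default)."""
        state = PlantState(m_EC_S=0.0, m_EN_S=0.0, m_EC_R=2.0, m_EN_R=2.0)
        ledger = flux_ledger(0.0, state, zero_env, plant_params)
        alive, event = starvation_check(state, ledger, plant_params)
        assert not alive
        assert event["organ"] == "S"

    def test_zero_resource_environment_kills_in_finite_time(self, plant_params, zero_env):
        state = PlantState(m_EC_S=0.1, m_EN_S=0.1, m_EC_R=0.1, m_EN_R=0.1)
        traj = simulate(
            state, zero_env, plant_params,
            SolverSettings(t_span=(0.0, 200.0), record_every=1.0),
        )
        assert traj.events, "no starvation event detected"
        etype, etime, payload = traj.events[0]
        assert etype == "terminal"
        assert 0.0 < etime < 200.0
        # reserves at (or below) the starvation threshold at the event
        final = traj.final_state
        eps = plant_params.eps_death
        assert final["m_EC_S"] <= eps * (1 + 1e-6)
        assert final["m_EN_S"] <= eps * (1 + 1e-6)


class TestDirectionalResponses:
    def test_nitrogen_shutoff_depletes_n_reserve_and_accumulates_carbon(
        self, plant_params
    ):
        """Cutting soil N drives N-reserve densities down and C-reserve
        densities up (carbon accumulates when nitrogen-limited)."""
        env = make_scenario(
            "step",
            dict(
                co2=4.0, light=4.0,
                soil_n=dict(before=4.0, after=0.0, t_switch=100.0),
                temperature=293.15,
            ),
        )
        traj = simulate(
            PlantState(), env, plant_params,
            SolverSettings(t_span=(0.0, 250.0), record_every=1.0),
        )
        i_switch = int(np.searchsorted(traj.times, 100.0))
        assert traj["m_EN_S"][-1] < traj["m_EN_S"][i_switch]
        assert traj["m_EN_R"][-1] < traj["m_EN_R"][i_switch]
        assert traj["m_EC_S"][-1] > traj["m_EC_S"][i_switch]
        assert traj["m_EC_R"][-1] > traj["m_EC_R"][i_switch]
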