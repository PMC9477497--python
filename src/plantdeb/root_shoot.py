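"""Generic two-organ (root-shoot) DEB model for plants.

The plant consists of two V1-morphic functional units.  The shoot acquires
all carbon (CO2 fixation, modulated by light), the root acquires all
nitrogen (standing in for every fine-root resource).  Each organ carries a
structure plus two reserves: a reduced-carbon reserve and a nitrogen-rich
reserve (organic, so it contains carbon as well).  Per right-hand-side
evaluation the flux cascade is

1. acquisition          - saturating uptake scaled by structural mass
2. mobilization         - first-order reserve turnover
3. maintenance + growth - maintenance paid from the C reserve flux first,
                          remainder feeds a parallel complementary growth SU;
                          a fixed fraction of synthesis becomes products
                          (wood: no maintenance, no turnover)
4. translocation        - each organ exports only the growth-SU rejection
                          (surplus) fluxes to its partner
5. reserve assembly     - N-rich reserve formation takes priority: its SU
                          rejects reduced carbon into the C reserve; the root
                          assembly SU combines shoot-derived CH2O with local
                          N uptake, the shoot SU combines photosynthate with
                          xylem-forwarded and root-rejected N
6. senescence           - structure turns over; a fraction of the lost C and
                          N is resorbed into the organ's own reserves, the
                          rest becomes litter

Every flux is recorded in a ledger, and cumulative pools (products, litter,
metabolic CO2, excreted N, assimilated C and N) are integrated alongside the
metabolic state so elemental closure can be audited to solver precision.

Units: time in days, carbon in C-mol, nitrogen in N-mol.  Reserve amounts
are tracked as densities (C-mol reserve per C-mol structure).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np

from plantdeb.environment import EnvironmentScenario, arrhenius_factor
from plantdeb.sim_engine import SolverSettings, Trajectory, integrate, params_hash
from plantdeb.su_kinetics import (
    SURule,
    SUSpec,
    production_rate,
    rejected_fluxes,
    saturating_uptake,
    scaled_arrivals,
)

__all__ = [
    "PlantParams",
    "PlantState",
    "STATE_NAMES",
    "acquisition",
    "assemble_reserves",
    "mobilization",
    "maintenance_and_growth",
    "translocate",
    "senesce_and_resorb",
    "derivatives",
    "make_rhs",
    "flux_ledger",
    "ledger_closure",
    "mass_balance_audit",
    "starvation_check",
    "starvation_event",
    "simulate",
]


@dataclass(frozen=True)
class PlantParams:
    """Physiological parameters of the root-shoot model.

    All rates are per day at the reference temperature; the Arrhenius factor
    ``exp(T_A/T_ref - T_A/T)`` multiplies every rate uniformly.  Values are
    normalized fixture defaults (half-saturations of 1, specific rates of
    order 0.01-1 per day) chosen so that the default scenarios support
    balanced exponential growth; they are not calibrated to any species.
    """

    j_CAm: float = 1.0      #: max specific CH2O assimilation, C-mol (C-mol shoot)^-1 d^-1
    j_NAm: float = 0.06     #: max specific N uptake, N-mol (C-mol root)^-1 d^-1
    K_C: float = 1.0        #: CO2 half-saturation (normalized env units)
    K_L: float = 1.0        #: light half-saturation
    K_N: float = 1.0        #: soil-N half-saturation
    nu_EC: float = 0.2      #: C-reserve turnover rate, d^-1
    nu_EN: float = 0.2      #: N-reserve turnover rate, d^-1
    p_M_S: float = 0.05     #: shoot specific maintenance, C-mol (C-mol structure)^-1 d^-1
    p_M_R: float = 0.05     #: root specific maintenance
    y_EC_V: float = 1.2     #: C-reserve C-mol per C-mol new structure
    y_EN_V: float = 0.3     #: N-reserve C-mol per C-mol new structure
    n_NV: float = 0.05      #: N:C ratio of structure, N-mol C-mol^-1
    n_NE: float = 0.25      #: N:C ratio of the N-rich reserve
    y_C_EN: float = 1.25    #: CH2O C-mol per C-mol N-reserve synthesized (>= 1)
    lambda_N: float = 0.5   #: fraction of root N uptake forwarded directly to the shoot SU
    kappa_P_S: float = 0.2  #: product fraction of shoot growth synthesis
    kappa_P_R: float = 0.1  #: product fraction of root growth synthesis
    h_V: float = 0.01       #: structure senescence rate, d^-1
    sigma: float = 0.5      #: resorbed fraction of senesced structure
    eta_T: float = 0.95     #: translocation efficiency, (0, 1]
    T_ref: float = 293.15   #: reference temperature, K
    T_A: float = 8000.0     #: Arrhenius temperature, K (shared by every rate)
    # Starvation threshold on reserve densities.  Senescence resorption
    # sustains a density floor of roughly h_V*sigma/nu (= 0.025 at the
    # defaults) even with zero assimilation, so the threshold must sit above
    # that floor for starvation death to be reachable at all.
    eps_death: float = 0.03
    light_mode: str = "multiplicative"  #: 'multiplicative' or 'pcsu' CO2 x light coupling
    allow_shrinkage: bool = False  #: pay unmet maintenance from structure

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "j_CAm", "j_NAm", "K_C", "K_L", "K_N", "nu_EC", "nu_EN",
            "p_M_S", "p_M_R", "y_EC_V", "y_EN_V", "n_NV", "n_NE", "y_C_EN",
            "h_V", "T_ref", "T_A", "eps_death",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                errors.append(f"{name} must be finite and nonnegative, got {v}")
        for name in ("j_CAm", "j_NAm", "K_C", "K_L", "K_N", "nu_EC", "nu_EN",
                     "y_EC_V", "y_EN_V", "n_NV", "n_NE", "y_C_EN", "T_ref"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be strictly positive")
        for name in ("lambda_N", "kappa_P_S", "kappa_P_R", "sigma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.eta_T <= 1.0:
            errors.append(f"eta_T must be in (0, 1], got {self.eta_T}")
        if self.y_C_EN < 1.0:
            errors.append(
                f"y_C_EN must be >= 1 (the N-rich reserve cannot contain more carbon "
                f"than was consumed to build it), got {self.y_C_EN}"
            )
        if self.y_EN_V * self.n_NE < self.n_NV - 1e-12:
            errors.append(
                "stoichiometric closure violated: y_EN_V * n_NE "
                f"({self.y_EN_V * self.n_NE:g}) < n_NV ({self.n_NV:g}); the N-reserve "
                "flux cannot supply the nitrogen content of new structure"
            )
        if self.n_NV > self.n_NE:
            errors.append(
                f"n_NV ({self.n_NV}) must not exceed n_NE ({self.n_NE}); resorbed "
                "nitrogen could not be stored as N-rich reserve otherwise"
            )
        if self.light_mode not in ("multiplicative", "pcsu"):
            errors.append(f"light_mode must be 'multiplicative' or 'pcsu', got {self.light_mode!r}")
        if errors:
            raise ValueError("invalid PlantParams:\n  " + "\n  ".join(errors))

    def growth_su(self) -> SUSpec:
        return SUSpec(SURule.PCSU, (self.y_EC_V, self.y_EN_V), label="growth")

    def assembly_su(self, organ: str) -> SUSpec:
        return SUSpec(SURule.PCSU, (self.y_C_EN, self.n_NE), label=f"assembly_{organ}")


STATE_NAMES = (
    "M_V_S", "M_V_R",
    "m_EC_S", "m_EN_S", "m_EC_R", "m_EN_R",
    "M_P", "M_litter_C", "M_litter_N", "M_CO2", "N_excess",
    "A_C_cum", "A_N_cum",
)


@dataclass
class PlantState:
    """Instantaneous state: structures, reserve densities, cumulative pools."""

    M_V_S: float = 0.1
    M_V_R: float = 0.1
    m_EC_S: float = 0.3
    m_EN_S: float = 0.1
    m_EC_R: float = 0.3
    m_EN_R: float = 0.1
    M_P: float = 0.0
    M_litter_C: float = 0.0
    M_litter_N: float = 0.0
    M_CO2: float = 0.0
    N_excess: float = 0.0
    A_C_cum: float = 0.0
    A_N_cum: float = 0.0
    alive: bool = True

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y, alive: bool = True) -> "PlantState":
        vals = {n: float(v) for n, v in zip(STATE_NAMES, y)}
        return cls(alive=alive, **vals)

    def validate(self) -> None:
        bad = [n for n in STATE_NAMES if getattr(self, n) < 0]
        if bad:
            raise ValueError(f"negative state components: {bad}")


# ---------------------------------------------------------------------------
# flux cascade
# ---------------------------------------------------------------------------

def acquisition(state: PlantState, env: dict, params: PlantParams) -> tuple[float, float]:
    """Assimilation fluxes (J_A_C in C-mol/d, J_A_N in N-mol/d).

    V1-morphy: both fluxes scale linearly with the acquiring organ's
    structural mass.  The shoot response to CO2 and light is multiplicative
    saturating by default, or a CO2 x light PCSU when
    ``params.light_mode == 'pcsu'``.
    """
    arr = arrhenius_factor(env["temperature"], params.T_ref, params.T_A)
    f_C = saturating_uptake(env["co2"], 1.0, params.K_C)
    f_L = saturating_uptake(env["light"], 1.0, params.K_L)
    f_N = saturating_uptake(env["soil_n"], 1.0, params.K_N)
    if params.light_mode == "multiplicative":
        f_shoot = f_C * f_L
    else:
        f_shoot = production_rate((f_C, f_L), SURule.PCSU)
    J_A_C = state.M_V_S * params.j_CAm * f_shoot * arr
    J_A_N = state.M_V_R * params.j_NAm * f_N * arr
    return J_A_C, J_A_N


def mobilization(state: PlantState, params: PlantParams, arr: float = 1.0) -> dict:
    """First-order catabolic fluxes from each reserve (C-mol/d)."""
    return {
        "mob_EC_S": params.nu_EC * state.m_EC_S * state.M_V_S * arr,
        "mob_EN_S": params.nu_EN * state.m_EN_S * state.M_V_S * arr,
        "mob_EC_R": params.nu_EC * state.m_EC_R * state.M_V_R * arr,
        "mob_EN_R": params.nu_EN * state.m_EN_R * state.M_V_R * arr,
    }


def maintenance_and_growth(
    J_EC: float, J_EN: float, maint_demand: float, kappa_P: float, params: PlantParams
) -> dict:
    """Organ-level maintenance payment, growth SU and surplus bookkeeping.

    Maintenance is paid from the mobilized C-reserve flux first, then from
    the carbon of the mobilized N-reserve flux; what remains feeds the
    parallel complementary growth SU with yields ``(y_EC_V, y_EN_V)``.  A
    fraction ``kappa_P`` of synthesis is diverted to products.  The SU
    rejection fluxes are the organ's surplus, to be shared with the partner.
    """
    if min(J_EC, J_EN, maint_demand) < 0:
        raise ValueError("maintenance_and_growth requires nonnegative fluxes")
    paid_C = min(J_EC, maint_demand)
    remainder = maint_demand - paid_C
    paid_N = min(J_EN, remainder)
    deficit = remainder - paid_N
    EC_avail = J_EC - paid_C
    EN_avail = J_EN - paid_N

    su = params.growth_su()
    rho = scaled_arrivals((EC_avail, EN_avail), su)
    j_syn = production_rate(rho, su.rule)
    rej = rejected_fluxes((EC_avail, EN_avail), su, j_syn)

    growth_struct = (1.0 - kappa_P) * j_syn
    growth_prod = kappa_P * j_syn
    growth_co2 = (params.y_EC_V + params.y_EN_V - 1.0) * j_syn
    n_consumed = params.y_EN_V * params.n_NE * j_syn
    growth_n_excess = n_consumed - params.n_NV * growth_struct - 0.0  # products carry no N
    return {
        "maint_paid_C": paid_C,
        "maint_paid_N": paid_N,
        "maint_deficit": deficit,
        "maint_n_excess": paid_N * params.n_NE,
        "growth_syn": j_syn,
        "growth_struct": growth_struct,
        "growth_prod": growth_prod,
        "growth_co2": growth_co2,
        "growth_n_excess": growth_n_excess,
        "surplus_EC": float(rej[0]),
        "surplus_EN": float(rej[1]),
    }


def translocate(
    surplus_EC_S: float, surplus_EN_S: float,
    surplus_EC_R: float, surplus_EN_R: float,
    params: PlantParams,
) -> dict:
    """Surplus-sharing translocation between the organs.

    Each organ exports only its growth-SU rejection fluxes.  The shoot's
    surplus carbon is delivered to the root assimilation SU (whose own
    rejection lands in the root C reserve); the other three surpluses arrive
    directly in the partner's corresponding reserve.  A fraction
    ``1 - eta_T`` of each transfer is lost in transit: its carbon respires to
    CO2, the nitrogen of N-reserve transfers is shed to litter.
    """
    eta = params.eta_T
    loss_frac = 1.0 - eta
    total_surplus = surplus_EC_S + surplus_EN_S + surplus_EC_R + surplus_EN_R
    return {
        "transloc_EC_StoR": eta * surplus_EC_S,  # into the root assembly SU
        "transloc_EN_StoR": eta * surplus_EN_S,
        "transloc_EC_RtoS": eta * surplus_EC_R,
        "transloc_EN_RtoS": eta * surplus_EN_R,
        "transloc_loss_C": loss_frac * total_surplus,
        "transloc_loss_N": loss_frac * (surplus_EN_S + surplus_EN_R) * params.n_NE,
    }


def assemble_reserves(
    J_A_C: float, J_A_N: float, C_to_root: float, params: PlantParams
) -> dict:
    """Priority formation of the nitrogen-rich reserves.

    Root assembly runs first: a PCSU combines shoot-derived CH2O with the
    local share ``(1 - lambda_N)`` of N uptake; rejected CH2O feeds the root
    C reserve, rejected N is forwarded to the shoot.  Shoot assembly then
    combines local photosynthate with ``lambda_N`` of the uptake plus the
    root-rejected N; shoot-rejected N is excreted (tracked in ``N_excess``).
    The carbon overhead ``y_C_EN - 1`` of each synthesis respires to CO2.
    """
    if min(J_A_C, J_A_N, C_to_root) < 0:
        raise ValueError("assemble_reserves requires nonnegative fluxes")
    su_R = params.assembly_su("root")
    in_C_R = C_to_root
    in_N_R = (1.0 - params.lambda_N) * J_A_N
    rho_R = scaled_arrivals((in_C_R, in_N_R), su_R)
    syn_R = production_rate(rho_R, su_R.rule)
    rej_R = rejected_fluxes((in_C_R, in_N_R), su_R, syn_R)

    su_S = params.assembly_su("shoot")
    in_C_S = J_A_C
    in_N_S = params.lambda_N * J_A_N + float(rej_R[1])
    rho_S = scaled_arrivals((in_C_S, in_N_S), su_S)
    syn_S = production_rate(rho_S, su_S.rule)
    rej_S = rejected_fluxes((in_C_S, in_N_S), su_S, syn_S)

    overhead = params.y_C_EN - 1.0
    return {
        "asm_R_in_C": in_C_R,
        "asm_R_in_N": in_N_R,
        "asm_R_syn": syn_R,
        "asm_R_rej_C": float(rej_R[0]),
        "asm_R_rej_N": float(rej_R[1]),
        "asm_R_co2": overhead * syn_R,
        "asm_S_in_C": in_C_S,
        "asm_S_in_N": in_N_S,
        "asm_S_syn": syn_S,
        "asm_S_rej_C": float(rej_S[0]),
        "asm_S_rej_N": float(rej_S[1]),
        "asm_S_co2": overhead * syn_S,
    }


def senesce_and_resorb(state: PlantState, params: PlantParams, arr: float = 1.0) -> dict:
    """Structure turnover with partial resorption into the organ's reserves.

    A fraction ``sigma`` of senesced structural carbon and nitrogen returns
    to the organ's own C and N reserves (the nitrogen as N-reserve
    C-equivalents via ``n_NE``); the remainder is litter.  Reserves carried
    by the senescing tissue (density times lost structure) go to litter
    without resorption.
    """
    out: dict[str, float] = {}
    lit_C = lit_N = 0.0
    for organ, M_V, m_EC, m_EN in (
        ("S", state.M_V_S, state.m_EC_S, state.m_EN_S),
        ("R", state.M_V_R, state.m_EC_R, state.m_EN_R),
    ):
        loss = params.h_V * M_V * arr
        resorb_EN = params.sigma * loss * params.n_NV / params.n_NE
        resorb_EC = params.sigma * loss - resorb_EN
        out[f"sen_loss_{organ}"] = loss
        out[f"resorb_EC_{organ}"] = resorb_EC
        out[f"resorb_EN_{organ}"] = resorb_EN
        out[f"sen_res_EC_{organ}"] = m_EC * params.h_V * M_V * arr
        out[f"sen_res_EN_{organ}"] = m_EN * params.h_V * M_V * arr
        lit_C += (1.0 - params.sigma) * loss
        lit_N += (1.0 - params.sigma) * loss * params.n_NV
    out["litter_struct_C"] = lit_C
    out["litter_struct_N"] = lit_N
    return out


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

def flux_ledger(
    t: float, state: PlantState, scenario: EnvironmentScenario, params: PlantParams
) -> dict:
    """Every instantaneous flux of one right-hand-side evaluation, by name."""
    env = scenario.at(t)
    arr = arrhenius_factor(env["temperature"], params.T_ref, params.T_A)
    J_A_C, J_A_N = acquisition(state, env, params)
    mob = mobilization(state, params, arr)

    mg_S = maintenance_and_growth(
        mob["mob_EC_S"], mob["mob_EN_S"], params.p_M_S * state.M_V_S * arr,
        params.kappa_P_S, params,
    )
    mg_R = maintenance_and_growth(
        mob["mob_EC_R"], mob["mob_EN_R"], params.p_M_R * state.M_V_R * arr,
        params.kappa_P_R, params,
    )
    tr = translocate(
        mg_S["surplus_EC"], mg_S["surplus_EN"],
        mg_R["surplus_EC"], mg_R["surplus_EN"], params,
    )
    asm = assemble_reserves(J_A_C, J_A_N, tr["transloc_EC_StoR"], params)
    sen = senesce_and_resorb(state, params, arr)

    ledger = {"J_A_C": J_A_C, "J_A_N": J_A_N}
    ledger.update(mob)
    for organ, mg in (("S", mg_S), ("R", mg_R)):
        for key, val in mg.items():
            ledger[f"{key}_{organ}"] = val
    ledger.update(tr)
    ledger.update(asm)
    ledger.update(sen)

    shrink_S = shrink_R = 0.0
    if params.allow_shrinkage:
        shrink_S = min(ledger["maint_deficit_S"], params.p_M_S * state.M_V_S * arr)
        shrink_R = min(ledger["maint_deficit_R"], params.p_M_R * state.M_V_R * arr)
    ledger["shrink_S"] = shrink_S
    ledger["shrink_R"] = shrink_R
    # reserves carried by shrinking structure follow it out (to litter)
    ledger["shrink_res_EC_S"] = state.m_EC_S * shrink_S
    ledger["shrink_res_EN_S"] = state.m_EN_S * shrink_S
    ledger["shrink_res_EC_R"] = state.m_EC_R * shrink_R
    ledger["shrink_res_EN_R"] = state.m_EN_R * shrink_R
    return ledger


def _state_derivative(state: PlantState, ledger: dict, params: PlantParams) -> np.ndarray:
    """Time derivative of the state vector from an evaluated ledger."""
    led = ledger
    d = dict.fromkeys(STATE_NAMES, 0.0)

    for organ, M_V in (("S", state.M_V_S), ("R", state.M_V_R)):
        growth = led[f"growth_struct_{organ}"]
        d[f"M_V_{organ}"] = growth - led[f"sen_loss_{organ}"] - led[f"shrink_{organ}"]
        if M_V > 0.0:
            if organ == "S":
                in_EC = led["asm_S_rej_C"] + led["transloc_EC_RtoS"] + led["resorb_EC_S"]
                in_EN = led["asm_S_syn"] + led["transloc_EN_RtoS"] + led["resorb_EN_S"]
            else:
                in_EC = led["asm_R_rej_C"] + led["resorb_EC_R"]
                in_EN = led["asm_R_syn"] + led["transloc_EN_StoR"] + led["resorb_EN_R"]
            m_EC = getattr(state, f"m_EC_{organ}")
            m_EN = getattr(state, f"m_EN_{organ}")
            d[f"m_EC_{organ}"] = (in_EC - led[f"mob_EC_{organ}"]) / M_V - m_EC * growth / M_V
            d[f"m_EN_{organ}"] = (in_EN - led[f"mob_EN_{organ}"]) / M_V - m_EN * growth / M_V

    d["M_P"] = led["growth_prod_S"] + led["growth_prod_R"]
    d["M_litter_C"] = (
        led["litter_struct_C"]
        + led["sen_res_EC_S"] + led["sen_res_EN_S"]
        + led["sen_res_EC_R"] + led["sen_res_EN_R"]
        + led["shrink_res_EC_S"] + led["shrink_res_EN_S"]
        + led["shrink_res_EC_R"] + led["shrink_res_EN_R"]
    )
    d["M_litter_N"] = (
        led["litter_struct_N"]
        + params.n_NE * (led["sen_res_EN_S"] + led["sen_res_EN_R"])
        + params.n_NE * (led["shrink_res_EN_S"] + led["shrink_res_EN_R"])
        + led["transloc_loss_N"]
    )
    d["M_CO2"] = (
        led["asm_S_co2"] + led["asm_R_co2"]
        + led["maint_paid_C_S"] + led["maint_paid_N_S"]
        + led["maint_paid_C_R"] + led["maint_paid_N_R"]
        + led["growth_co2_S"] + led["growth_co2_R"]
        + led["transloc_loss_C"]
        + led["shrink_S"] + led["shrink_R"]
    )
    d["N_excess"] = (
        led["asm_S_rej_N"]
        + led["growth_n_excess_S"] + led["growth_n_excess_R"]
        + led["maint_n_excess_S"] + led["maint_n_excess_R"]
        + params.n_NV * (led["shrink_S"] + led["shrink_R"])
    )
    d["A_C_cum"] = led["J_A_C"]
    d["A_N_cum"] = led["J_A_N"]
    return np.array([d[n] for n in STATE_NAMES])


def derivatives(
    t: float, state: PlantState, scenario: EnvironmentScenario, params: PlantParams
) -> tuple[np.ndarray, dict]:
    """Full right-hand side: time derivatives of the state vector plus ledger.

    A dead plant has zero derivatives.  Non-finite values anywhere raise with
    the ledger attached for debugging.
    """
    if not state.alive:
        return np.zeros(len(STATE_NAMES)), {}
    ledger = flux_ledger(t, state, scenario, params)
    dydt = _state_derivative(state, ledger, params)
    if not np.all(np.isfinite(dydt)):
        raise FloatingPointError(
            f"non-finite derivative at t={t}: {dict(zip(STATE_NAMES, dydt))}; ledger={ledger}"
        )
    return dydt, ledger


def ledger_closure(ledger: dict, params: PlantParams) -> tuple[float, float]:
    """Instantaneous elemental closure residuals (C-mol/d, N-mol/d) of a ledger.

    Sums every signed carbon and nitrogen entry; both residuals are zero to
    rounding for any ledger the model emits.  Used as the independent oracle
    for the right-hand-side wiring and for fault injection in tests.
    """
    led = ledger
    dC_struct = (
        led["growth_struct_S"] + led["growth_struct_R"]
        - led["sen_loss_S"] - led["sen_loss_R"]
        - led["shrink_S"] - led["shrink_R"]
    )
    res_flows = {
        "EC_S": led["asm_S_rej_C"] + led["transloc_EC_RtoS"] + led["resorb_EC_S"]
        - led["mob_EC_S"] - led["sen_res_EC_S"] - led["shrink_res_EC_S"],
        "EN_S": led["asm_S_syn"] + led["transloc_EN_RtoS"] + led["resorb_EN_S"]
        - led["mob_EN_S"] - led["sen_res_EN_S"] - led["shrink_res_EN_S"],
        "EC_R": led["asm_R_rej_C"] + led["resorb_EC_R"]
        - led["mob_EC_R"] - led["sen_res_EC_R"] - led["shrink_res_EC_R"],
        "EN_R": led["asm_R_syn"] + led["transloc_EN_StoR"] + led["resorb_EN_R"]
        - led["mob_EN_R"] - led["sen_res_EN_R"] - led["shrink_res_EN_R"],
    }
    dC_res = sum(res_flows.values())
    dP = led["growth_prod_S"] + led["growth_prod_R"]
    dCO2 = (
        led["asm_S_co2"] + led["asm_R_co2"]
        + led["maint_paid_C_S"] + led["maint_paid_N_S"]
        + led["maint_paid_C_R"] + led["maint_paid_N_R"]
        + led["growth_co2_S"] + led["growth_co2_R"]
        + led["transloc_loss_C"] + led["shrink_S"] + led["shrink_R"]
    )
    dLit_C = (
        led["litter_struct_C"]
        + led["sen_res_EC_S"] + led["sen_res_EN_S"]
        + led["sen_res_EC_R"] + led["sen_res_EN_R"]
        + led["shrink_res_EC_S"] + led["shrink_res_EN_S"]
        + led["shrink_res_EC_R"] + led["shrink_res_EN_R"]
    )
    resid_C = led["J_A_C"] - (dC_struct + dC_res + dP + dCO2 + dLit_C)

    dN_struct = params.n_NV * dC_struct
    dN_res = params.n_NE * (res_flows["EN_S"] + res_flows["EN_R"])
    dLit_N = (
        led["litter_struct_N"]
        + params.n_NE * (led["sen_res_EN_S"] + led["sen_res_EN_R"])
        + params.n_NE * (led["shrink_res_EN_S"] + led["shrink_res_EN_R"])
        + led["transloc_loss_N"]
    )
    dN_x = (
        led["asm_S_rej_N"]
        + led["growth_n_excess_S"] + led["growth_n_excess_R"]
        + led["maint_n_excess_S"] + led["maint_n_excess_R"]
        + params.n_NV * (led["shrink_S"] + led["shrink_R"])
    )
    resid_N = led["J_A_N"] - (dN_struct + dN_res + dLit_N + dN_x)
    return resid_C, resid_N


# ---------------------------------------------------------------------------
# integration helpers
# ---------------------------------------------------------------------------

def make_rhs(
    scenario: EnvironmentScenario, params: PlantParams
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vector right-hand side for the simulation engine."""

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        state = PlantState.from_vector(np.clip(y, 0.0, None))
        dydt, _ = derivatives(t, state, scenario, params)
        return dydt

    return rhs


def starvation_check(
    state: PlantState, ledger: dict, params: PlantParams
) -> tuple[bool, dict | None]:
    """Carbon-starvation death rule.

    The plant dies when an organ cannot pay its maintenance costs while both
    of its reserves are depleted (densities below ``eps_death``).  Returns
    ``(alive, event_record)``.
    """
    for organ in ("S", "R"):
        deficit = ledger.get(f"maint_deficit_{organ}", 0.0)
        m_EC = getattr(state, f"m_EC_{organ}")
        m_EN = getattr(state, f"m_EN_{organ}")
        if deficit > 0.0 and m_EC < params.eps_death and m_EN < params.eps_death:
            return False, {"organ": organ, "deficit": deficit}
    return True, None


def starvation_event(
    scenario: EnvironmentScenario, params: PlantParams
) -> Callable[[float, np.ndarray], float]:
    """Terminal event function: positive once the starvation rule triggers.

    For each organ the indicator is the minimum of (maintenance deficit,
    eps_death - m_EC, eps_death - m_EN); the event fires when the larger of
    the two organ indicators crosses zero from below.
    """

    def event(t: float, y: np.ndarray) -> float:
        state = PlantState.from_vector(np.clip(y, 0.0, None))
        ledger = flux_ledger(t, state, scenario, params)
        worst = -1.0
        for organ in ("S", "R"):
            s = min(
                ledger[f"maint_deficit_{organ}"],
                params.eps_death - getattr(state, f"m_EC_{organ}"),
                params.eps_death - getattr(state, f"m_EN_{organ}"),
            )
            worst = max(worst, s)
        return worst

    event.terminal = True
    event.direction = 1
    event.name = "starvation"
    return event


def simulate(
    state0: PlantState,
    scenario: EnvironmentScenario,
    params: PlantParams,
    settings: SolverSettings,
    detect_starvation: bool = True,
) -> Trajectory:
    """Integrate the root-shoot model and attach ledgers and metadata."""
    state0.validate()
    rhs = make_rhs(scenario, params)

    def ledger_fn(t: float, y: np.ndarray) -> dict:
        return flux_ledger(t, PlantState.from_vector(np.clip(y, 0.0, None)), scenario, params)

    events = [starvation_event(scenario, params)] if detect_starvation else None
    meta = {
        "model": "root_shoot",
        "scenario": scenario.label,
        "params_hash": params_hash(asdict(params)),
        "seed": scenario.seed,
    }
    return integrate(
        rhs,
        state0.to_vector(),
        settings,
        state_names=STATE_NAMES,
        ledger_fn=ledger_fn,
        events=events,
        metadata=meta,
    )


def mass_balance_audit(
    trajectory: Trajectory, params: PlantParams
) -> tuple[float, float]:
    """Worst-case relative carbon and nitrogen closure errors of a trajectory.

    Two independent checks are combined: (i) cumulative closure -- the change
    in total tracked carbon (structures + reserves + products + CO2 + litter)
    must equal cumulative assimilation, and likewise for nitrogen including
    the excreted pool; (ii) instantaneous closure of every recorded ledger
    (signed flux sums must vanish), normalized by the assimilation flux.
    """
    y = trajectory.states
    idx = {n: i for i, n in enumerate(trajectory.state_names)}
    M_V_S, M_V_R = y[:, idx["M_V_S"]], y[:, idx["M_V_R"]]
    res_C = (y[:, idx["m_EC_S"]] + y[:, idx["m_EN_S"]]) * M_V_S + (
        y[:, idx["m_EC_R"]] + y[:, idx["m_EN_R"]]
    ) * M_V_R
    C_total = (
        M_V_S + M_V_R + res_C + y[:, idx["M_P"]] + y[:, idx["M_CO2"]] + y[:, idx["M_litter_C"]]
    )
    resid_C = (C_total - C_total[0]) - (y[:, idx["A_C_cum"]] - y[0, idx["A_C_cum"]])
    scale_C = max(float(C_total[0]), float(np.max(y[:, idx["A_C_cum"]])), 1e-300)
    err_C = float(np.max(np.abs(resid_C))) / scale_C

    N_res = params.n_NE * (y[:, idx["m_EN_S"]] * M_V_S + y[:, idx["m_EN_R"]] * M_V_R)
    N_total = (
        params.n_NV * (M_V_S + M_V_R)
        + N_res
        + y[:, idx["M_litter_N"]]
        + y[:, idx["N_excess"]]
    )
    resid_N = (N_total - N_total[0]) - (y[:, idx["A_N_cum"]] - y[0, idx["A_N_cum"]])
    scale_N = max(float(N_total[0]), float(np.max(y[:, idx["A_N_cum"]])), 1e-300)
    err_N = float(np.max(np.abs(resid_N))) / scale_N

    if trajectory.ledgers is not None:
        for _, row in trajectory.ledgers.iterrows():
            rc, rn = ledger_closure(row.to_dict(), params)
            flux_scale_C = max(float(row.get("J_A_C", 0.0)), 1.0)
            flux_scale_N = max(float(row.get("J_A_N", 0.0)), 1.0)
            err_C = max(err_C, abs(rc) / flux_scale_C)
            err_N = max(err_N, abs(rn) / flux_scale_N)
    return err_C, err_N
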