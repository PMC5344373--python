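"""Dynamic flux balance analysis for a multi-species batch culture.

Each species is a stoichiometric model whose growth-limiting uptake
reactions carry irreversible Michaelis-Menten kinetics,

    v_upt = Vmax * [S] / (Km + [S]),

used as the flux *upper bound* at the current medium concentration.  At
every time step each species' biomass flux is optimised independently by
(parsimonious) FBA, and biomasses and shared metabolite concentrations
are integrated forward:

    dX_i/dt = mu_i X_i,        dS_j/dt = sum_i s_ij v_ij X_i.

The default integrator is fixed-step explicit Euler with uptake capping:
a species may not withdraw more of a metabolite within one step than the
pool holds, so concentrations never go negative and reruns are bitwise
reproducible.  An adaptive mode (scipy RK45) is available but not the
default, because adaptive stiff integration of an LP-embedded right-hand
side is solver-order dependent.

Units: time h, concentrations mM, biomass gDW/L, fluxes mmol/gDW/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CompiledLP, ModelError

__all__ = [
    "UptakeKinetics",
    "CommunityState",
    "TimeCourse",
    "SimulationConfig",
    "uptake_rate",
    "community_rhs",
    "simulate_batch",
    "condition_preset",
    "interaction_yields",
]


@dataclass(frozen=True)
class UptakeKinetics:
    """Michaelis-Menten parameters bounding one uptake reaction.

    ``substrate_id`` names the external metabolite whose concentration
    drives the bound (inferred from the reaction stoichiometry when the
    reaction is a plain exchange).
    """

    reaction_id: str
    vmax: float  # mmol/gDW/h
    km: float  # mM
    substrate_id: str | None = None

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("Vmax must be >= 0")
        if self.km <= 0:
            raise ValueError("Km must be > 0")


def uptake_rate(kin: UptakeKinetics, S: float) -> float:
    """Michaelis-Menten uptake bound at substrate concentration ``S`` (mM)."""
    if S < 0:
        raise ValueError(f"negative substrate concentration: {S}")
    return kin.vmax * S / (kin.km + S)


@dataclass
class CommunityState:
    time: float
    biomass: dict[str, float]  # species -> gDW/L
    concentration: dict[str, float]  # shared metabolite -> mM

    def validate(self) -> None:
        for sp, x in self.biomass.items():
            if x < 0:
                raise ValueError(f"negative biomass for {sp}: {x}")
        for met, s in self.concentration.items():
            if s < -1e-9:
                raise ValueError(f"negative concentration for {met}: {s}")


@dataclass
class SimulationConfig:
    t_end: float = 30.0
    dt: float = 0.01
    integrator: str = "euler_fixed"  # euler_fixed | adaptive
    lp_mode: str = "parsimonious"  # parsimonious | plain
    seed: int = 0  # consumed only by downstream noise models

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.integrator not in ("euler_fixed", "adaptive"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.lp_mode not in ("parsimonious", "plain"):
            raise ValueError(f"unknown lp_mode {self.lp_mode!r}")


@dataclass
class TimeCourse:
    """Trajectory of a batch simulation.

    ``fluxes[sp][rxn][k]`` is the specific flux used over the step that
    starts at ``times[k]`` (the final entry repeats the last solved step so
    all arrays share one length).
    """

    times: np.ndarray
    species: list[str]
    biomass: dict[str, np.ndarray]
    concentration: dict[str, np.ndarray]
    growth_rate: dict[str, np.ndarray]
    fluxes: dict[str, dict[str, np.ndarray]]
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt_grid(self) -> np.ndarray:
        return np.diff(self.times)

    def state_at(self, k: int) -> CommunityState:
        return CommunityState(
            time=float(self.times[k]),
            biomass={sp: float(self.biomass[sp][k]) for sp in self.species},
            concentration={m: float(v[k]) for m, v in self.concentration.items()},
        )

    def cumulative_flux(self, species: str, rxn_id: str) -> float:
        """Time-integrated flux * biomass (mmol per litre of culture)."""
        v = self.fluxes[species][rxn_id][:-1]
        x = self.biomass[species][:-1]
        return float(np.sum(v * x * self.dt_grid))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, variable, species, value, units)."""
        rows = []
        for sp in self.species:
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "variable": "biomass",
                        "species": sp,
                        "value": self.biomass[sp],
                        "units": "gDW/L",
                    }
                )
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "variable": "growth_rate",
                        "species": sp,
                        "value": self.growth_rate[sp],
                        "units": "1/h",
                    }
                )
            )
        for met, vals in self.concentration.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "variable": met,
                        "species": "medium",
                        "value": vals,
                        "units": "mM",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


def _species_bounds(
    sp,
    compiled: CompiledLP,
    conc: Mapping[str, float],
    X: float,
    dt: float,
    extra_caps: Mapping[tuple[str, str], float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step flux bounds: kinetic Michaelis-Menten caps plus pool-
    availability caps so no metabolite can be overdrawn within ``dt``."""
    lb = compiled.lb.copy()
    ub = compiled.ub.copy()
    idx = compiled.model._rxn_index
    for kin in sp.uptake_kinetics:
        j = idx[kin.reaction_id]
        S = conc.get(_kinetics_substrate(sp, kin), 0.0)
        ub[j] = min(ub[j], uptake_rate(kin, max(S, 0.0)))
        lb[j] = min(lb[j], ub[j])
    if X > 0 and dt > 0:
        for met_id, consumers in sp.model.external_stoich().items():
            S = conc.get(met_id)
            if S is None:
                continue
            for rxn_id, coef in consumers.items():
                if coef >= 0:
                    continue
                j = idx[rxn_id]
                cap = S / (abs(coef) * X * dt)
                if extra_caps and (met_id, rxn_id) in extra_caps:
                    cap = min(cap, extra_caps[(met_id, rxn_id)])
                ub[j] = min(ub[j], max(cap, 0.0))
                lb[j] = min(lb[j], ub[j])
    return lb, ub


def _kinetics_substrate(sp, kin: UptakeKinetics) -> str:
    if kin.substrate_id is not None:
        return kin.substrate_id
    rxn = sp.model.reaction(kin.reaction_id)
    ext = [
        m
        for m, c in rxn.stoich.items()
        if c < 0 and sp.model.metabolite(m).compartment == "external"
    ]
    if len(ext) != 1:
        raise ModelError(
            f"cannot infer substrate for kinetics on {kin.reaction_id!r}; "
            "set substrate_id explicitly"
        )
    return ext[0]


def _solve_step(
    community,
    compiled: dict[str, CompiledLP],
    state: CommunityState,
    dt: float,
    lp_mode: str,
) -> tuple[dict[str, float], dict[str, dict[str, float]], dict[str, float]]:
    """Solve all species' FBAs at one state.

    Returns (growth rates, per-species flux dicts, concentration
    derivatives).  Uses up to three fair-sharing passes when several
    species jointly overdraw a scarce pool within the step.
    """
    parsimonious = lp_mode == "parsimonious"
    mu: dict[str, float] = {}
    fluxes: dict[str, dict[str, float]] = {}
    extra_caps: dict[str, dict[tuple[str, str], float]] = {sp.species_name: {} for sp in community.species}

    for _ in range(3):
        for sp in community.species:
            X = state.biomass[sp.species_name]
            if X <= 0:
                mu[sp.species_name] = 0.0
                fluxes[sp.species_name] = {r: 0.0 for r in sp.model.reaction_ids}
                continue
            lb, ub = _species_bounds(
                sp, compiled[sp.species_name], state.concentration, X, dt,
                extra_caps[sp.species_name],
            )
            sol = compiled[sp.species_name].solve(lb, ub, parsimonious=parsimonious)
            if sol.status == "optimal":
                mu[sp.species_name] = max(sol.objective_value, 0.0)
                fluxes[sp.species_name] = dict(sol.fluxes)
            elif sol.status == "infeasible":
                # dormancy: no growth, no fluxes, no maintenance
                mu[sp.species_name] = 0.0
                fluxes[sp.species_name] = {r: 0.0 for r in sp.model.reaction_ids}
            else:
                raise RuntimeError(
                    f"FBA for {sp.species_name} returned status {sol.status} "
                    f"at t={state.time:.3f} h; state snapshot: {state}"
                )
        if dt <= 0:
            break
        overdraw = _detect_overdraw(community, state, fluxes, dt, extra_caps)
        if not overdraw:
            break

    dS = _concentration_derivatives(community, state, fluxes)
    return mu, fluxes, dS


def _detect_overdraw(community, state, fluxes, dt, extra_caps) -> bool:
    """Tighten per-consumer caps (proportional fair share) for any pool that
    would be jointly overdrawn in this step; returns True if re-solve needed."""
    draw: dict[str, float] = {}
    contrib: dict[str, list[tuple[str, str, float, float]]] = {}
    for sp in community.species:
        X = state.biomass[sp.species_name]
        if X <= 0:
            continue
        for met_id, touching in sp.model.external_stoich().items():
            if met_id not in state.concentration:
                continue
            for rxn_id, coef in touching.items():
                v = fluxes[sp.species_name].get(rxn_id, 0.0)
                take = -coef * v * X * dt  # positive = consumed
                if take > 0:
                    draw[met_id] = draw.get(met_id, 0.0) + take
                    contrib.setdefault(met_id, []).append(
                        (sp.species_name, rxn_id, take, coef)
                    )
    tightened = False
    for met_id, total in draw.items():
        pool = state.concentration[met_id]
        if total <= pool * (1 + 1e-12) + 1e-15:
            continue
        tightened = True
        for sp_name, rxn_id, take, coef in contrib[met_id]:
            share = pool * take / total
            X = state.biomass[sp_name]
            extra_caps[sp_name][(met_id, rxn_id)] = share / (abs(coef) * X * dt)
    return tightened


def _concentration_derivatives(community, state, fluxes) -> dict[str, float]:
    dS = {m: 0.0 for m in state.concentration}
    for sp in community.species:
        X = state.biomass[sp.species_name]
        if X <= 0:
            continue
        for met_id, touching in sp.model.external_stoich().items():
            if met_id not in dS:
                continue
            acc = 0.0
            for rxn_id, coef in touching.items():
                acc += coef * fluxes[sp.species_name].get(rxn_id, 0.0)
            dS[met_id] += acc * X
    return dS


def community_rhs(
    state: CommunityState,
    community,
    config: SimulationConfig,
    compiled: dict[str, CompiledLP] | None = None,
):
    """Derivatives (dX_i/dt, dS_j/dt) at one state.

    Species whose FBA is infeasible contribute mu = 0 and zero fluxes.
    """
    state.validate()
    if compiled is None:
        compiled = _compile(community)
    mu, fluxes, dS = _solve_step(
        community, compiled, state, config.dt, config.lp_mode
    )
    dX = {sp: mu[sp] * state.biomass[sp] for sp in state.biomass}
    return dX, dS, mu, fluxes


def _compile(community) -> dict[str, CompiledLP]:
    return {
        sp.species_name: CompiledLP(sp.model, sp.ratio_constraints)
        for sp in community.species
    }


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


def simulate_batch(
    community,
    initial: CommunityState,
    config: SimulationConfig | None = None,
) -> TimeCourse:
    """Integrate the community over ``[0, t_end]`` in batch.

    Deterministic: identical inputs give bitwise-identical trajectories.
    """
    config = config or SimulationConfig()
    initial.validate()
    if config.integrator == "adaptive":
        return _simulate_adaptive(community, initial, config)
    compiled = _compile(community)
    n_steps = int(round(config.t_end / config.dt))
    species = [sp.species_name for sp in community.species]
    mets = list(initial.concentration)
    times = np.linspace(0.0, n_steps * config.dt, n_steps + 1)

    X = {sp: np.empty(n_steps + 1) for sp in species}
    S = {m: np.empty(n_steps + 1) for m in mets}
    MU = {sp: np.empty(n_steps + 1) for sp in species}
    V = {
        sp.species_name: {r: np.empty(n_steps + 1) for r in sp.model.reaction_ids}
        for sp in community.species
    }
    for sp in species:
        X[sp][0] = initial.biomass[sp]
    for m in mets:
        S[m][0] = initial.concentration[m]

    state = CommunityState(
        0.0, dict(initial.biomass), dict(initial.concentration)
    )
    for k in range(n_steps + 1):
        mu, fluxes, dS = _solve_step(
            community, compiled, state, config.dt, config.lp_mode
        )
        for sp in species:
            MU[sp][k] = mu[sp]
            for r, v in fluxes[sp].items():
                V[sp][r][k] = v
        if k == n_steps:
            break
        for sp in species:
            state.biomass[sp] = state.biomass[sp] * (1.0 + mu[sp] * config.dt)
            X[sp][k + 1] = state.biomass[sp]
        for m in mets:
            nxt = state.concentration[m] + dS[m] * config.dt
            if nxt < -1e-6:
                raise RuntimeError(
                    f"metabolite {m} driven to {nxt:.3e} mM at t="
                    f"{state.time:.3f} h despite uptake capping; use a "
                    f"smaller dt than {config.dt}"
                )
            state.concentration[m] = max(nxt, 0.0)
            S[m][k + 1] = state.concentration[m]
        state.time = times[k + 1]

    return TimeCourse(
        times=times,
        species=species,
        biomass=X,
        concentration=S,
        growth_rate=MU,
        fluxes=V,
        meta={"config": config},
    )


def _simulate_adaptive(community, initial, config: SimulationConfig) -> TimeCourse:
    """Adaptive RK45 integration; output resampled on the fixed dt grid."""
    from scipy.integrate import solve_ivp

    compiled = _compile(community)
    species = [sp.species_name for sp in community.species]
    mets = list(initial.concentration)
    y0 = np.array(
        [initial.biomass[sp] for sp in species]
        + [initial.concentration[m] for m in mets]
    )

    def rhs(t, y):
        st = CommunityState(
            t,
            {sp: max(y[i], 0.0) for i, sp in enumerate(species)},
            {m: max(y[len(species) + j], 0.0) for j, m in enumerate(mets)},
        )
        mu, fluxes, dS = _solve_step(community, compiled, st, 0.0, config.lp_mode)
        return np.array(
            [mu[sp] * st.biomass[sp] for sp in species]
            + [dS[m] for m in mets]
        )

    t_eval = np.arange(0.0, config.t_end + config.dt / 2, config.dt)
    sol = solve_ivp(
        rhs, (0.0, config.t_end), y0, t_eval=t_eval, method="RK45",
        max_step=10 * config.dt,
    )
    X = {sp: np.maximum(sol.y[i], 0.0) for i, sp in enumerate(species)}
    S = {m: np.maximum(sol.y[len(species) + j], 0.0) for j, m in enumerate(mets)}
    MU = {sp: np.empty(len(sol.t)) for sp in species}
    V = {
        sp.species_name: {r: np.empty(len(sol.t)) for r in sp.model.reaction_ids}
        for sp in community.species
    }
    for k, t in enumerate(sol.t):
        st = CommunityState(
            t, {sp: X[sp][k] for sp in species}, {m: S[m][k] for m in mets}
        )
        mu, fluxes, _ = _solve_step(community, compiled, st, 0.0, config.lp_mode)
        for sp in species:
            MU[sp][k] = mu[sp]
            for r, v in fluxes[sp].items():
                V[sp][r][k] = v
    return TimeCourse(
        times=sol.t, species=species, biomass=X, concentration=S,
        growth_rate=MU, fluxes=V, meta={"config": config},
    )


# ---------------------------------------------------------------------------
# condition presets and yields
# ---------------------------------------------------------------------------


def condition_preset(name: str, carry_over_no3: float = 0.0):
    """Initial state and exchange openness for one nitrogen regime.

    ``name`` is one of NH4_NO3, NH4, NO3, N2.  ``carry_over_no3`` adds
    residual nitrate (mM) from the pre-culture to any condition.
    """
    from . import config as _config

    return _config.condition(name, carry_over_no3=carry_over_no3)


def interaction_yields(tc: TimeCourse, community) -> dict[str, dict[str, float]]:
    """Cumulative exchange yields per species, normalised to the species'
    reference uptake (glucose for the fermenter, H2 for the respirer).

    Values are mol per mol of reference substrate consumed over the run;
    ``biomass`` is gDW per mmol.  Production is positive, net consumption
    negative.
    """
    out: dict[str, dict[str, float]] = {}
    for sp in community.species:
        name = sp.species_name
        ref = sp.reference_uptake
        ref_total = tc.cumulative_flux(name, ref)
        if ref_total <= 0:
            # dormant species (e.g. the H2 consumer without an electron
            # acceptor) are omitted rather than poisoning the whole report
            continue
        yields: dict[str, float] = {}
        ext = sp.model.external_stoich()
        for met_id, touching in ext.items():
            net = 0.0
            for rxn_id, coef in touching.items():
                net += coef * tc.cumulative_flux(name, rxn_id)
            yields[met_id] = net / ref_total
        dx = tc.biomass[name][-1] - tc.biomass[name][0]
        yields["biomass"] = dx / ref_total
        out[name] = yields
    if not out:
        raise ValueError(
            "no species consumed its reference substrate over this trajectory"
        )
    return out
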