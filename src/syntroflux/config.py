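"""Condition presets, fitted parameters and scenario assembly.

The four nitrogen regimes of the batch experiment are encoded here as
media recipes (converted from g/L to mM) plus the per-condition fitted
parameters: glucose-uptake Vmax of the fermenter and the two flux-ratio
constraints (butyrate/acetate production, NH4+/NO2- consumption).  The
flat parameter dictionary produced by :func:`default_parameters` is the
single surface the fitting module perturbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .community import (
    CommunityModel,
    build_clostridium_coarse,
    build_wolinella_coarse,
    couple_models,
)
from .dfba import CommunityState

__all__ = [
    "CONDITIONS",
    "SHARED_METABOLITES",
    "Condition",
    "condition",
    "default_parameters",
    "build_community",
    "initial_state",
    "load_params",
    "save_params",
]

CONDITIONS = ("NH4_NO3", "NH4", "NO3", "N2")

SHARED_METABOLITES = [
    "glc_e", "ac_e", "but_e", "co2_e", "h2_e", "for_e",
    "no3_e", "no2_e", "nh4_e", "n2_e",
]

# --- media recipe (g/L -> mM) ---------------------------------------------
_MW_GLUCOSE_MONOHYDRATE = 198.17
_MW_NH4CL = 53.49
_MW_NANO3 = 84.995

GLUCOSE_MM = 0.59 / _MW_GLUCOSE_MONOHYDRATE * 1000  # 2.977 mM
NH4_MM = 0.25 / _MW_NH4CL * 1000  # 4.674 mM
NO3_MM = 0.85 / _MW_NANO3 * 1000  # 10.00 mM

#: residual nitrite and acetate carried over with the 1:100 inoculum from
#: the actively fermenting/respiring pre-culture (mM); they seed the
#: cross-feeding loop in the nitrate-containing conditions and are dwarfed
#: by in-culture production within hours.
NO2_CARRYOVER_MM = 0.05
AC_CARRYOVER_MM = 0.05

#: headspace N2 treated as a non-limiting pool in the N2 condition
N2_POOL_MM = 1000.0

#: inoculum (1:100 from a grown culture), gDW/L.  The co-culture was
#: pre-adapted by serial transfer before the experiment, so the inoculum
#: carries the species at their balanced-growth composition (~11:1
#: fermenter:respirer by dry weight), not at 1:1.
X0_CLOSTRIDIUM_GDW_PER_L = 0.002
X0_WOLINELLA_GDW_PER_L = 0.00018

# --- per-condition fitted parameters --------------------------------------
# Glucose-uptake Vmax varies between conditions; the two ratio constraints
# encode the observed (suboptimal) branching.  Values were calibrated so
# that the simulated co-culture reproduces the inferred exchange yields
# and growth-rate ratios; see docs/methods.md.
_GLUCOSE_VMAX = {"NH4_NO3": 5.0, "NH4": 5.5, "NO3": 5.0, "N2": 3.0}
_RATIO_BUT_AC = {"NH4_NO3": 2.6705, "NH4": 4.2658, "NO3": 0.22224, "N2": 2.0}
_RATIO_NH4_NO2 = {"NH4_NO3": 0.63970, "NH4": None, "NO3": None, "N2": None}


@dataclass
class Condition:
    """A nitrogen regime: initial state plus the fitted parameter set."""

    name: str
    initial_state: CommunityState
    parameters: dict[str, float | None] = field(default_factory=dict)


def default_parameters(name: str) -> dict[str, float | None]:
    """Flat parameter dictionary for one condition (the fitting surface)."""
    if name not in CONDITIONS:
        raise ValueError(f"unknown condition {name!r}; choose from {CONDITIONS}")
    return {
        "clostridium.glucose_vmax": _GLUCOSE_VMAX[name],
        "clostridium.glucose_km": 0.2,
        "clostridium.no2_vmax": 4.0,
        "clostridium.no2_km": 0.01,
        "clostridium.nh4_vmax": 5.0,
        "clostridium.nh4_km": 0.05,
        "wolinella.h2_vmax": 80.0,
        "wolinella.h2_km": 0.001,
        "wolinella.no3_vmax": 80.0,
        "wolinella.no3_km": 0.1,
        "wolinella.acetate_vmax": 15.0,
        "wolinella.acetate_km": 0.01,
        "wolinella.nh4_vmax": 5.0,
        "wolinella.nh4_km": 0.05,
        "wolinella.no2_vmax": 5.0,
        "wolinella.no2_km": 0.05,
        "ratio.butyrate_acetate": _RATIO_BUT_AC[name],
        "ratio.nh4_no2": _RATIO_NH4_NO2[name],
        "clostridium.biomass_atp": None,  # None -> model default
        "clostridium.biomass_nh4": None,
        "wolinella.biomass_atp": None,
        "wolinella.biomass_nh4": None,
        "wolinella.biomass_acetate": None,
        "wolinella.nar_atp_yield": None,
        "init.x0_clostridium": X0_CLOSTRIDIUM_GDW_PER_L,
        "init.x0_wolinella": X0_WOLINELLA_GDW_PER_L,
    }


def initial_state(name: str, carry_over_no3: float = 0.0,
                  params: dict | None = None) -> CommunityState:
    """Initial concentrations (mM) and biomasses for one condition."""
    if name not in CONDITIONS:
        raise ValueError(f"unknown condition {name!r}; choose from {CONDITIONS}")
    conc = {m: 0.0 for m in SHARED_METABOLITES}
    conc["glc_e"] = GLUCOSE_MM
    conc["ac_e"] = AC_CARRYOVER_MM
    if name in ("NH4_NO3", "NH4"):
        conc["nh4_e"] = NH4_MM
    if name in ("NH4_NO3", "NO3"):
        conc["no3_e"] = NO3_MM
        conc["no2_e"] = NO2_CARRYOVER_MM
    if name == "N2":
        conc["n2_e"] = N2_POOL_MM
    conc["no3_e"] += carry_over_no3
    p = params or {}
    biomass = {
        "clostridium": p.get("init.x0_clostridium", X0_CLOSTRIDIUM_GDW_PER_L),
        "wolinella": p.get("init.x0_wolinella", X0_WOLINELLA_GDW_PER_L),
    }
    return CommunityState(time=0.0, biomass=biomass, concentration=conc)


def condition(name: str, carry_over_no3: float = 0.0,
              params: dict | None = None) -> Condition:
    merged = default_parameters(name)
    if params:
        merged.update(params)
    return Condition(
        name=name,
        initial_state=initial_state(name, carry_over_no3, merged),
        parameters=merged,
    )


def build_community(
    cond: Condition | str,
    species: tuple[str, ...] = ("clostridium", "wolinella"),
    optimal: bool = False,
) -> CommunityModel:
    """Assemble the community for a condition.

    ``optimal=True`` releases the fitted ratio constraints (the
    unconstrained-optimum scenario); uptake kinetics are retained.
    """
    if isinstance(cond, str):
        cond = condition(cond)
    p = cond.parameters

    def _opt(key):
        return {} if p.get(key) is None else p[key]

    members = []
    if "clostridium" in species:
        branching = None if optimal else {
            "butyrate_acetate": p.get("ratio.butyrate_acetate"),
            "nh4_no2": p.get("ratio.nh4_no2"),
        }
        biomass = {}
        if p.get("clostridium.biomass_atp") is not None:
            biomass["atp"] = p["clostridium.biomass_atp"]
        if p.get("clostridium.biomass_nh4") is not None:
            biomass["nh4"] = p["clostridium.biomass_nh4"]
        members.append(
            build_clostridium_coarse(
                branching_params=branching,
                biomass_params=biomass or None,
                kinetics={
                    "glucose": (p["clostridium.glucose_vmax"],
                                p["clostridium.glucose_km"]),
                    "no2": (p["clostridium.no2_vmax"], p["clostridium.no2_km"]),
                    "nh4": (p["clostridium.nh4_vmax"], p["clostridium.nh4_km"]),
                },
            )
        )
    if "wolinella" in species:
        biomass = {}
        if p.get("wolinella.biomass_atp") is not None:
            biomass["atp"] = p["wolinella.biomass_atp"]
        if p.get("wolinella.biomass_nh4") is not None:
            biomass["nh4"] = p["wolinella.biomass_nh4"]
        if p.get("wolinella.biomass_acetate") is not None:
            biomass["acetate"] = p["wolinella.biomass_acetate"]
        kwargs = {}
        if p.get("wolinella.nar_atp_yield") is not None:
            kwargs["nar_atp_yield"] = p["wolinella.nar_atp_yield"]
        members.append(
            build_wolinella_coarse(
                biomass_params=biomass or None,
                kinetics={
                    "h2": (p["wolinella.h2_vmax"], p["wolinella.h2_km"]),
                    "no3": (p["wolinella.no3_vmax"], p["wolinella.no3_km"]),
                    "acetate": (p["wolinella.acetate_vmax"],
                                p["wolinella.acetate_km"]),
                    "nh4": (p["wolinella.nh4_vmax"], p["wolinella.nh4_km"]),
                    "no2": (p["wolinella.no2_vmax"], p["wolinella.no2_km"]),
                },
                **kwargs,
            )
        )
    shared = [
        m for m in SHARED_METABOLITES
        if any(m in sp.model.external_stoich() for sp in members)
    ]
    return couple_models(members, shared)


def save_params(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def load_params(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"parameter file {path} does not hold a mapping")
    return out
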