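"""Coarse-grained species models and their coupling into a community.

Two anaerobes exchanging hydrogen, nitrite and acetate:

* *Clostridium acetobutylicum* — ferments glucose to acetate, butyrate,
  CO2 and H2.  Reduced ferredoxin is a conserved moiety feeding both the
  hydrogenase and the nitrite reductase, so NO2- assimilation competes
  directly with H2 production (6 electrons per NO2- reduced to NH4+
  versus 2 per H2).  Nitrogenase allows growth on N2 at a steep ATP cost.
* *Wolinella succinogenes* — respires H2 (or formate) with nitrate,
  gaining ATP from NO3- -> NO2- reduction, and assimilates acetate as its
  carbon source.  It cannot grow without an electron acceptor.

The models are deliberately coarse: pathway segments are lumped into
single net reactions, and ATP/NAD(H)/ferredoxin are element-free
bookkeeping tokens whose steady-state rows enforce moiety closure.  All
carbon- and nitrogen-carrying metabolites are element-balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    DEFAULT_BOUND,
    Metabolite,
    Reaction,
    RatioConstraint,
    StoichModel,
    ModelError,
    build_model,
)
from .dfba import UptakeKinetics

__all__ = [
    "SpeciesModel",
    "CommunityModel",
    "build_wolinella_coarse",
    "build_clostridium_coarse",
    "couple_models",
    "BIOMASS_CARBON_MMOL_PER_GDW",
    "BIOMASS_NITROGEN_MMOL_PER_GDW",
]

# Biomass elemental composition CH1.8O0.5N0.2 (24.626 g per mol C):
# carbon and nitrogen content per gram dry weight.
BIOMASS_CARBON_MMOL_PER_GDW = 40.607
BIOMASS_NITROGEN_MMOL_PER_GDW = 8.121

# --- default biomass demands (mmol per gDW) -------------------------------
# Precursor demands follow from the elemental composition (pyruvate and
# acetate carry the biomass carbon for the fermenter and the respirer
# respectively); the ATP and NAD(P)H demands were calibrated so that the
# fitted co-culture reproduces the observed exchange yields (see
# docs/methods.md for the calibration).
CLOSTRIDIUM_BIOMASS = {
    "pyruvate": 13.536,  # = 40.607 mmol C / 3 C per pyruvate
    "nadh": 2.637,
    "atp": 42.669,
    "nh4": 8.121,
}
WOLINELLA_BIOMASS = {
    "acetate": 20.304,  # = 40.607 mmol C / 2 C per acetate
    "nh4": 8.121,
    "atp": 200.0,
}

#: ATP gained per NO3- reduced to NO2- with H2 as electron donor
#: (electron-transport phosphorylation; literature-derived default).
NAR_ATP_YIELD = 1.0

#: ATP cost of nitrite transport/assimilation in the fermenter; makes
#: NO2- use strictly growth-penalising so that an unconstrained optimum
#: prefers NH4+ (as observed for the genome-scale network).
NO2_UPTAKE_ATP_COST = 0.1

_FORMULAS = {
    "glc": {"C": 6, "H": 12, "O": 6},
    "pyr": {"C": 3, "H": 4, "O": 3},
    "accoa": {"C": 2, "H": 3, "O": 1},
    "ac": {"C": 2, "H": 4, "O": 2},
    "but": {"C": 4, "H": 8, "O": 2},
    "co2": {"C": 1, "O": 2},
    "h2": {"H": 2},
    "for": {"C": 1, "H": 2, "O": 2},
    "no3": {"N": 1, "O": 3},
    "no2": {"N": 1, "O": 2},
    "nh4": {"N": 1, "H": 4},
    "n2": {"N": 2},
}
_TOKENS = ("atp", "adp", "nad", "nadh", "fdox", "fdred")


@dataclass
class SpeciesModel:
    """One species: stoichiometric model plus its dynamic configuration."""

    model: StoichModel
    species_name: str
    biomass_reaction: str
    uptake_kinetics: list[UptakeKinetics] = field(default_factory=list)
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    #: exchange used to normalise this species' yields
    reference_uptake: str = ""
    #: gDW per unit of biomass flux (biomass demands are per gDW, so 1)
    molar_mass_biomass: float = 1.0

    def __post_init__(self) -> None:
        rxn_ids = set(self.model.reaction_ids)
        for kin in self.uptake_kinetics:
            if kin.reaction_id not in rxn_ids:
                raise ModelError(
                    f"{self.species_name}: kinetics reference unknown reaction "
                    f"{kin.reaction_id!r}"
                )

    def without_ratio_constraints(self) -> "SpeciesModel":
        return SpeciesModel(
            model=self.model,
            species_name=self.species_name,
            biomass_reaction=self.biomass_reaction,
            uptake_kinetics=list(self.uptake_kinetics),
            ratio_constraints=[],
            reference_uptake=self.reference_uptake,
            molar_mass_biomass=self.molar_mass_biomass,
        )


@dataclass
class CommunityModel:
    species: list[SpeciesModel]
    shared_metabolites: list[str]
    #: (species name, reaction id) -> shared metabolite id
    exchange_map: dict[tuple[str, str], str]

    def species_by_name(self, name: str) -> SpeciesModel:
        for sp in self.species:
            if sp.species_name == name:
                return sp
        raise KeyError(name)


def _mets(ids_internal, ids_external):
    mets = []
    for mid in ids_internal:
        base = mid
        mets.append(
            Metabolite(
                mid,
                compartment="internal",
                formula={} if base in _TOKENS else _FORMULAS.get(base),
            )
        )
    for mid in ids_external:
        base = mid[:-2] if mid.endswith("_e") else mid
        mets.append(
            Metabolite(mid, compartment="external", formula=_FORMULAS.get(base))
        )
    return mets


def build_wolinella_coarse(
    biomass_params: dict | None = None,
    nar_atp_yield: float = NAR_ATP_YIELD,
    kinetics: dict[str, tuple[float, float]] | None = None,
) -> SpeciesModel:
    """Eight-reaction coarse-grained model of *W. succinogenes*.

    Reactions: H2 uptake, formate oxidation (closed by default, none was
    detected), NO3- uptake, NO3- -> NO2- respiration (ATP-yielding),
    NO2- -> NH4+ reduction (assimilatory route when no NH4+ is supplied),
    acetate uptake (carbon source), NH4+ uptake, biomass.

    ``biomass_params``: acetate/NH4+/ATP demand per gDW (positive).
    ``kinetics``: {substrate: (Vmax, Km)} for h2, no3, acetate, nh4.
    """
    bp = dict(WOLINELLA_BIOMASS)
    if biomass_params:
        bp.update(biomass_params)
    if any(v <= 0 for v in bp.values()):
        raise ModelError("biomass demands must be positive")
    kin = {
        "h2": (80.0, 0.001),
        "no3": (80.0, 0.1),
        "acetate": (15.0, 0.01),
        "nh4": (5.0, 0.05),
        "no2": (5.0, 0.05),
    }
    if kinetics:
        kin.update(kinetics)

    metabolites = _mets(
        ["h2", "no3", "ac", "nh4", "atp", "adp"],
        ["h2_e", "for_e", "co2_e", "no3_e", "no2_e", "ac_e", "nh4_e"],
    )
    reactions = [
        Reaction("EX_h2", {"h2_e": -1, "h2": 1}, 0, DEFAULT_BOUND, is_exchange=True,
                 name="H2 uptake"),
        Reaction("FDH", {"for_e": -1, "h2": 1, "co2_e": 1}, 0, 0,
                 name="formate oxidation (closed: no formate detected)"),
        Reaction("EX_no3", {"no3_e": -1, "no3": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="NO3- uptake"),
        Reaction("NAR", {"h2": -1, "no3": -1, "adp": -nar_atp_yield,
                         "no2_e": 1, "atp": nar_atp_yield},
                 0, DEFAULT_BOUND, name="NO3- respiration (H2 -> NO2- + ATP)"),
        Reaction("NRF", {"no2_e": -1, "h2": -3, "nh4": 1}, 0, DEFAULT_BOUND,
                 name="NO2- reduction to NH4+ (assimilatory)"),
        Reaction("EX_ac", {"ac_e": -1, "ac": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="acetate uptake (carbon source)"),
        Reaction("EX_nh4", {"nh4_e": -1, "nh4": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="NH4+ uptake"),
        Reaction(
            "BIOMASS",
            {"ac": -bp["acetate"], "nh4": -bp["nh4"], "atp": -bp["atp"],
             "adp": bp["atp"]},
            0, DEFAULT_BOUND, name="biomass",
        ),
    ]
    model = build_model(metabolites, reactions, "BIOMASS")
    return SpeciesModel(
        model=model,
        species_name="wolinella",
        biomass_reaction="BIOMASS",
        uptake_kinetics=[
            UptakeKinetics("EX_h2", *kin["h2"]),
            UptakeKinetics("EX_no3", *kin["no3"]),
            UptakeKinetics("EX_ac", *kin["acetate"]),
            UptakeKinetics("EX_nh4", *kin["nh4"]),
            UptakeKinetics("NRF", *kin["no2"], substrate_id="no2_e"),
        ],
        reference_uptake="EX_h2",
    )


def build_clostridium_coarse(
    branching_params: dict | None = None,
    biomass_params: dict | None = None,
    kinetics: dict[str, tuple[float, float]] | None = None,
    no2_atp_cost: float = NO2_UPTAKE_ATP_COST,
) -> SpeciesModel:
    """Coarse-grained surrogate of the *C. acetobutylicum* fermentation
    network with an explicit ferredoxin moiety.

    ``branching_params`` may carry the fitted flux ratios
    ``butyrate_acetate`` (butyrate/acetate production) and ``nh4_no2``
    (NH4+/NO2- consumption); they are attached as strict equality ratio
    constraints and can be released for the optimal-behaviour analysis.
    """
    bp = dict(CLOSTRIDIUM_BIOMASS)
    if biomass_params:
        bp.update(biomass_params)
    if any(v <= 0 for v in bp.values()):
        raise ModelError("biomass demands must be positive")
    kin = {"glucose": (5.0, 0.2), "no2": (4.0, 0.01), "nh4": (5.0, 0.05)}
    if kinetics:
        kin.update(kinetics)

    metabolites = _mets(
        ["glc", "pyr", "accoa", "ac", "but", "co2", "h2", "no2", "nh4", "n2",
         "atp", "adp", "nad", "nadh", "fdox", "fdred"],
        ["glc_e", "ac_e", "but_e", "co2_e", "h2_e", "no2_e", "nh4_e", "n2_e"],
    )
    reactions = [
        Reaction("EX_glc", {"glc_e": -1, "glc": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="glucose uptake"),
        Reaction("GLYC", {"glc": -1, "adp": -2, "nad": -2,
                          "pyr": 2, "atp": 2, "nadh": 2},
                 0, DEFAULT_BOUND, name="glycolysis (glucose -> 2 pyruvate)"),
        Reaction("PFOR", {"pyr": -1, "fdox": -1, "accoa": 1, "co2": 1,
                          "fdred": 1},
                 0, DEFAULT_BOUND, name="pyruvate:ferredoxin oxidoreductase"),
        Reaction("HYD", {"fdred": -1, "fdox": 1, "h2": 1}, 0, DEFAULT_BOUND,
                 name="ferredoxin hydrogenase"),
        Reaction("FNOR", {"nadh": -1, "fdox": -1, "nad": 1, "fdred": 1},
                 -DEFAULT_BOUND, DEFAULT_BOUND,
                 name="NADH <-> ferredoxin transhydrogenation"),
        Reaction("ACK", {"accoa": -1, "adp": -1, "ac": 1, "atp": 1},
                 0, DEFAULT_BOUND, name="acetate branch (+1 ATP)"),
        Reaction("BUK", {"accoa": -2, "nadh": -2, "adp": -1,
                         "but": 1, "nad": 2, "atp": 1},
                 0, DEFAULT_BOUND, name="butyrate branch (+1 ATP)"),
        Reaction("NIR", {"no2": -1, "fdred": -3, "atp": -no2_atp_cost,
                         "nh4": 1, "fdox": 3, "adp": no2_atp_cost},
                 0, DEFAULT_BOUND, name="nitrite reductase (NO2- -> NH4+)"),
        Reaction("NIF", {"n2": -1, "fdred": -4, "atp": -16,
                         "nh4": 2, "h2": 1, "fdox": 4, "adp": 16},
                 0, DEFAULT_BOUND,
                 name="nitrogenase (N2 + 8e- + 16 ATP -> 2 NH4+ + H2)"),
        Reaction("ATPM", {"atp": -1, "adp": 1}, 0, DEFAULT_BOUND,
                 name="ATP hydrolysis valve"),
        Reaction(
            "BIOMASS",
            {"pyr": -bp["pyruvate"], "nadh": -bp["nadh"], "atp": -bp["atp"],
             "nh4": -bp["nh4"], "nad": bp["nadh"], "adp": bp["atp"]},
            0, DEFAULT_BOUND, name="biomass",
        ),
        Reaction("EX_ac", {"ac": -1, "ac_e": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="acetate export"),
        Reaction("EX_but", {"but": -1, "but_e": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="butyrate export"),
        Reaction("EX_co2", {"co2": -1, "co2_e": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="CO2 export"),
        Reaction("EX_h2", {"h2": -1, "h2_e": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="H2 export"),
        Reaction("EX_no2", {"no2_e": -1, "no2": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="NO2- uptake"),
        Reaction("EX_nh4", {"nh4_e": -1, "nh4": 1}, -DEFAULT_BOUND,
                 DEFAULT_BOUND, is_exchange=True,
                 name="NH4+ uptake (reversible: ammonification allowed)"),
        Reaction("EX_n2", {"n2_e": -1, "n2": 1}, 0, DEFAULT_BOUND,
                 is_exchange=True, name="N2 uptake"),
    ]
    model = build_model(metabolites, reactions, "BIOMASS")

    ratio_constraints = []
    if branching_params:
        if branching_params.get("butyrate_acetate") is not None:
            ratio_constraints.append(
                RatioConstraint("EX_but", "EX_ac",
                                branching_params["butyrate_acetate"])
            )
        if branching_params.get("nh4_no2") is not None:
            ratio_constraints.append(
                RatioConstraint("EX_nh4", "EX_no2", branching_params["nh4_no2"])
            )
    return SpeciesModel(
        model=model,
        species_name="clostridium",
        biomass_reaction="BIOMASS",
        uptake_kinetics=[
            UptakeKinetics("EX_glc", *kin["glucose"]),
            UptakeKinetics("EX_no2", *kin["no2"]),
            UptakeKinetics("EX_nh4", *kin["nh4"]),
        ],
        ratio_constraints=ratio_constraints,
        reference_uptake="EX_glc",
    )


def couple_models(
    species_models: list[SpeciesModel],
    shared_ids: list[str],
) -> CommunityModel:
    """Couple species through a shared extracellular pool.

    Every shared metabolite must be produced or consumed by at least one
    species; an unresolvable id raises :class:`ModelError`.  A single
    species forms a valid degenerate (monoculture) community.
    """
    exchange_map: dict[tuple[str, str], str] = {}
    touched: dict[str, int] = {m: 0 for m in shared_ids}
    for sp in species_models:
        ext = sp.model.external_stoich()
        for met_id in shared_ids:
            if met_id in ext and ext[met_id]:
                touched[met_id] += 1
                for rxn_id in ext[met_id]:
                    exchange_map[(sp.species_name, rxn_id)] = met_id
    orphans = [m for m, n in touched.items() if n == 0]
    if orphans:
        raise ModelError(
            f"shared metabolites with no producer and no consumer: {orphans}"
        )
    return CommunityModel(
        species=list(species_models),
        shared_metabolites=list(shared_ids),
        exchange_map=exchange_map,
    )
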