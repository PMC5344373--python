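"""SBML Level 3 + FBC import/export for stoichiometric models.

Round-trips preserve reaction count, stoichiometry, bounds and the
objective exactly.  Exchange reactions are tagged with SBO:0000627 so the
flag survives the round-trip even for lumped reactions that touch an
external species without being exchanges.
"""

from __future__ import annotations

import warnings

import libsbml

from .core import Metabolite, Reaction, StoichModel, ModelError

__all__ = ["write_sbml", "read_sbml", "sbml_io"]

_SBO_EXCHANGE = "SBO:0000627"


def _formula_string(formula) -> str | None:
    if formula is None:
        return None
    parts = []
    for el in sorted(formula):
        n = formula[el]
        if n == int(n):
            n = int(n)
        parts.append(f"{el}{'' if n == 1 else n}")
    return "".join(parts)


def _parse_formula(s: str) -> dict[str, float]:
    import re

    out: dict[str, float] = {}
    for el, n in re.findall(r"([A-Z][a-z]?)([0-9]*\.?[0-9]*)", s):
        out[el] = float(n) if n else 1.0
    return out


def write_sbml(model: StoichModel, path: str) -> None:
    """Serialise a model as SBML L3V1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    m = doc.createModel()
    m.setId("model")
    mfbc = m.getPlugin("fbc")
    mfbc.setStrict(True)

    for comp_id in ("internal", "external"):
        c = m.createCompartment()
        c.setId(comp_id)
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        s = m.createSpecies()
        s.setId(met.id)
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(met.compartment == "external")
        s.setConstant(False)
        if met.formula is not None:
            sfbc = s.getPlugin("fbc")
            formula = _formula_string(met.formula)
            if formula:
                sfbc.setChemicalFormula(formula)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bound_{len(bound_params)}"
            p = m.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        if rxn.is_exchange:
            r.setSBOTerm(_SBO_EXCHANGE)
        for met_id, coef in rxn.stoich.items():
            if coef < 0:
                sr = r.createReactant()
            else:
                sr = r.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = r.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(rxn.upper_bound))

    if model.objective_id is not None:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str) -> StoichModel:
    """Read an SBML L3 (FBC) model.

    A file without an FBC objective is read successfully with the
    objective left unset (a warning is emitted); such a model can be
    inspected but not optimised until an objective is assigned.
    """
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelError(
                    f"SBML parse error in {path}: {err.getMessage()}"
                )
    m = doc.getModel()
    if m is None:
        raise ModelError(f"no model found in {path}")
    if doc.getLevel() < 3:
        raise ModelError(
            f"unsupported SBML level {doc.getLevel()}; level 3 required"
        )

    metabolites = []
    for i in range(m.getNumSpecies()):
        s = m.getSpecies(i)
        comp = s.getCompartment()
        if comp not in ("internal", "external"):
            comp = "external" if s.getBoundaryCondition() else "internal"
        formula = None
        sfbc = s.getPlugin("fbc")
        if sfbc is not None and sfbc.isSetChemicalFormula():
            formula = _parse_formula(sfbc.getChemicalFormula())
        metabolites.append(
            Metabolite(s.getId(), name=s.getName(), compartment=comp,
                       formula=formula)
        )

    params = {
        m.getParameter(i).getId(): m.getParameter(i).getValue()
        for i in range(m.getNumParameters())
    }
    reactions = []
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = r.getPlugin("fbc")
        lb, ub = -1e30, 1e30
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
        is_exchange = r.getSBOTermID() == _SBO_EXCHANGE
        reactions.append(
            Reaction(r.getId(), stoich, lb, ub, is_exchange=is_exchange,
                     name=r.getName())
        )

    objective_id = None
    mfbc = m.getPlugin("fbc")
    if mfbc is not None and mfbc.getNumObjectives() > 0:
        obj = mfbc.getActiveObjective() or mfbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if objective_id is None:
        warnings.warn(
            f"{path}: no FBC objective found; model read with objective "
            "unset", stacklevel=2,
        )
    return StoichModel(metabolites, reactions, objective_id)


def sbml_io(path: str, direction: str, model: StoichModel | None = None):
    """Unified read/write entry point (``direction``: 'read' | 'write')."""
    if direction == "write":
        if model is None:
            raise ValueError("writing requires a model")
        write_sbml(model, path)
        return None
    if direction == "read":
        return read_sbml(path)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")
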