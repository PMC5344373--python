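"""Stoichiometric models and flux balance analysis as linear programmes.

A :class:`StoichModel` holds metabolites, reactions and an objective
(biomass) reaction.  Flux balance analysis (FBA) maximises the objective
flux subject to the steady-state constraint ``S v = 0`` over *internal*
metabolites, flux bounds, and optional :class:`RatioConstraint` equalities
that pin the proportion of two fluxes (e.g. butyrate/acetate production).

Alternate optima are resolved with a parsimonious secondary objective:
among all flux vectors attaining the optimum, the one minimising the sum
of absolute fluxes is returned, which makes reported flux vectors unique
and reruns bitwise reproducible.

Units follow the constraint-based convention used throughout the package:
fluxes in mmol·gDW⁻¹·h⁻¹ (the biomass flux, scaled to 1 gDW per unit, is
the specific growth rate in h⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DEFAULT_BOUND",
    "FLUX_TOL",
    "Metabolite",
    "Reaction",
    "StoichModel",
    "RatioConstraint",
    "FBASolution",
    "ElementBalanceReport",
    "ModelError",
    "build_model",
    "check_element_balance",
    "solve_fba",
    "solve_fba_parsimonious",
]

#: Cap used for "unbounded" reactions so a truly unbounded LP signals a
#: modelling bug rather than silently growing without limit.
DEFAULT_BOUND = 1000.0

#: LP feasibility/optimality tolerance; reported fluxes below this are
#: truncated to exactly zero.
FLUX_TOL = 1e-9

#: Elements exempt from the balance check.  H and O imbalances can always
#: be closed by free exchange of protons and water, which the coarse
#: models do not track explicitly.
_EXEMPT_ELEMENTS = frozenset({"H", "O"})
_EXEMPT_METABOLITES = frozenset({"h", "h2o", "H+", "H2O"})


class ModelError(ValueError):
    """Raised for structurally invalid models or constraints."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species, either inside a cell or in the shared medium.

    ``formula`` maps element symbol to count; an empty dict denotes an
    element-free bookkeeping token (ATP, NAD(H), ferredoxin), ``None``
    means the composition is unknown and reactions using it cannot be
    balance-checked.
    """

    id: str
    name: str = ""
    compartment: str = "internal"
    formula: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.compartment not in ("internal", "external"):
            raise ModelError(
                f"metabolite {self.id!r}: compartment must be 'internal' or "
                f"'external', got {self.compartment!r}"
            )
        if self.formula is not None:
            for el, n in self.formula.items():
                if n < 0:
                    raise ModelError(
                        f"metabolite {self.id!r}: negative count for element {el}"
                    )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds.

    Sign convention: uptake exchanges are written ``A_ext -> A`` so that a
    positive flux means consumption from the medium (matching the positive
    ``v_upt`` of the Michaelis-Menten uptake bound); production exchanges
    are written ``A -> A_ext``.
    """

    id: str
    stoich: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class RatioConstraint:
    """Linear equality ``v_num - ratio * v_den = 0``.

    Encodes a fitted, strictly enforced branching proportion such as the
    butyrate/acetate production ratio.
    """

    numerator_id: str
    denominator_id: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ModelError("ratio constraints require ratio >= 0")


@dataclass(frozen=True)
class FBASolution:
    fluxes: Mapping[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class ElementBalanceReport:
    """Outcome of :func:`check_element_balance`.

    ``unbalanced`` lists reactions with a non-zero net element count
    (H/O excepted); ``uncheckable`` lists reactions that could not be
    audited (exchanges, the biomass reaction, or reactions touching a
    metabolite of unknown composition).
    """

    unbalanced: list[str] = field(default_factory=list)
    uncheckable: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.unbalanced)

    def __len__(self) -> int:
        return len(self.unbalanced)


class StoichModel:
    """Stoichiometric model of one species.

    The steady-state matrix covers *internal* metabolites only; external
    (medium) metabolites are source/sink pools handled by the dynamic
    layer and are excluded from the ``S v = 0`` rows.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_id: str | None,
    ) -> None:
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.objective_id = objective_id
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._internal_ids = [
            m.id for m in self.metabolites if m.compartment == "internal"
        ]
        self._matrix: np.ndarray | None = None
        self._external_stoich: dict[str, dict[str, float]] | None = None

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return list(self._internal_ids)

    @property
    def matrix(self) -> np.ndarray:
        """Internal-metabolite x reaction coefficient matrix."""
        if self._matrix is None:
            rows = {m: i for i, m in enumerate(self._internal_ids)}
            S = np.zeros((len(self._internal_ids), len(self.reactions)))
            for j, rxn in enumerate(self.reactions):
                for met_id, coef in rxn.stoich.items():
                    i = rows.get(met_id)
                    if i is not None:
                        S[i, j] = coef
            self._matrix = S
        return self._matrix

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # external stoichiometry, used by the dynamic layer ---------------------
    def external_stoich(self) -> dict[str, dict[str, float]]:
        """Map external metabolite id -> {reaction id: coefficient} (cached)."""
        if self._external_stoich is None:
            ext = {m.id for m in self.metabolites if m.compartment == "external"}
            out: dict[str, dict[str, float]] = {e: {} for e in ext}
            for rxn in self.reactions:
                for met_id, coef in rxn.stoich.items():
                    if met_id in ext:
                        out[met_id][rxn.id] = coef
            self._external_stoich = out
        return self._external_stoich

    def equation_table(self) -> str:
        """Plain-text tabular dump (id, equation, lb, ub) for diffing."""
        lines = []
        for r in self.reactions:
            lhs = " + ".join(
                f"{-c:g} {m}" for m, c in sorted(r.stoich.items()) if c < 0
            )
            rhs = " + ".join(
                f"{c:g} {m}" for m, c in sorted(r.stoich.items()) if c > 0
            )
            lines.append(
                f"{r.id}\t{lhs or '∅'} --> {rhs or '∅'}\t{r.lower_bound:g}\t{r.upper_bound:g}"
            )
        return "\n".join(lines)


def build_model(
    metabolites: Sequence[Metabolite],
    reactions: Sequence[Reaction],
    objective_id: str,
) -> StoichModel:
    """Validate and assemble a :class:`StoichModel`.

    Raises :class:`ModelError` on duplicate ids, dangling metabolite
    references, a missing objective, or an exchange reaction that does not
    touch exactly one external metabolite.
    """
    met_ids = [m.id for m in metabolites]
    if len(set(met_ids)) != len(met_ids):
        dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
        raise ModelError(f"duplicate metabolite ids: {dup}")
    rxn_ids = [r.id for r in reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        raise ModelError(f"duplicate reaction ids: {dup}")
    known = set(met_ids)
    ext = {m.id for m in metabolites if m.compartment == "external"}
    for rxn in reactions:
        missing = set(rxn.stoich) - known
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references undeclared metabolites: "
                f"{sorted(missing)}"
            )
        if rxn.is_exchange:
            n_ext = sum(1 for m in rxn.stoich if m in ext)
            if n_ext != 1:
                raise ModelError(
                    f"exchange reaction {rxn.id!r} must touch exactly one "
                    f"external metabolite (touches {n_ext})"
                )
    if objective_id not in set(rxn_ids):
        raise ModelError(f"objective reaction {objective_id!r} not in model")
    return StoichModel(metabolites, reactions, objective_id)


def check_element_balance(model: StoichModel) -> ElementBalanceReport:
    """Audit element conservation reaction by reaction.

    Exchange reactions and the biomass (objective) reaction move material
    across the system boundary and are reported as uncheckable, as is any
    reaction involving a metabolite without a formula.  H and O are not
    audited: proton and water exchange (not modelled explicitly) can close
    any H/O imbalance, so only C, N, S, P, ... are conserved quantities.
    """
    report = ElementBalanceReport()
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.objective_id:
            report.uncheckable.append(rxn.id)
            continue
        net: dict[str, float] = {}
        checkable = True
        for met_id, coef in rxn.stoich.items():
            if met_id in _EXEMPT_METABOLITES:
                continue
            formula = model.metabolite(met_id).formula
            if formula is None:
                checkable = False
                break
            for el, n in formula.items():
                if el in _EXEMPT_ELEMENTS:
                    continue
                net[el] = net.get(el, 0.0) + coef * n
        if not checkable:
            report.uncheckable.append(rxn.id)
        elif any(abs(v) > 1e-9 for v in net.values()):
            report.unbalanced.append(rxn.id)
    return report


# ---------------------------------------------------------------------------
# LP machinery
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


class CompiledLP:
    """Pre-assembled LP arrays for one model + fixed set of ratio constraints.

    The dynamic layer re-solves the same FBA thousands of times with only
    the bounds changing; compiling the equality system once keeps the
    per-step cost down to the HiGHS call itself.
    """

    def __init__(
        self,
        model: StoichModel,
        extra_constraints: Iterable[RatioConstraint] = (),
    ) -> None:
        self.model = model
        n = len(model.reactions)
        rows = [model.matrix]
        for rc in extra_constraints:
            if rc.numerator_id not in model._rxn_index:
                raise ModelError(f"ratio constraint: unknown reaction {rc.numerator_id!r}")
            if rc.denominator_id not in model._rxn_index:
                raise ModelError(f"ratio constraint: unknown reaction {rc.denominator_id!r}")
            row = np.zeros((1, n))
            row[0, model._rxn_index[rc.numerator_id]] = 1.0
            row[0, model._rxn_index[rc.denominator_id]] = -rc.ratio
            rows.append(row)
        self.A_eq = np.vstack(rows)
        self.b_eq = np.zeros(self.A_eq.shape[0])
        self.n = n
        if model.objective_id is None:
            raise ModelError("model has no objective reaction set")
        self.obj_idx = model._rxn_index[model.objective_id]
        self.c = np.zeros(n)
        self.c[self.obj_idx] = -1.0  # linprog minimises
        self.lb, self.ub = model.bounds_arrays()
        # parsimonious stage: variables [v, s], minimise sum(s), s >= |v|
        m_eq = self.A_eq.shape[0]
        self._p_A_eq = np.hstack([self.A_eq, np.zeros((m_eq, n))])
        eye = np.eye(n)
        self._p_A_ub = np.vstack(
            [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
        )
        self._p_b_ub = np.zeros(2 * n)
        self._p_c = np.concatenate([np.zeros(n), np.ones(n)])

    def solve(
        self,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
        parsimonious: bool = True,
    ) -> FBASolution:
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        bounds = np.column_stack([lb, ub])
        res = linprog(
            self.c, A_eq=self.A_eq, b_eq=self.b_eq, bounds=bounds, method="highs"
        )
        status = _STATUS.get(res.status, "infeasible")
        if status != "optimal":
            return FBASolution(fluxes={}, objective_value=np.nan, status=status)
        opt = -res.fun
        if parsimonious:
            v = self._solve_parsimonious(lb, ub, opt)
        else:
            v = res.x
        v = np.where(np.abs(v) < FLUX_TOL, 0.0, v)
        fluxes = dict(zip(self.model.reaction_ids, v))
        return FBASolution(fluxes=fluxes, objective_value=float(v[self.obj_idx]), status="optimal")

    def _solve_parsimonious(self, lb: np.ndarray, ub: np.ndarray, opt: float) -> np.ndarray:
        n = self.n
        amax = float(np.max(np.abs(np.concatenate([lb, ub])))) + 1.0
        # pin the objective at its optimum; widen by the LP tolerance only
        # if the exact pin is numerically infeasible
        for slack in (0.0, FLUX_TOL):
            lb2 = lb.copy()
            ub2 = ub.copy()
            lb2[self.obj_idx] = opt - slack
            ub2[self.obj_idx] = opt + slack
            bounds = np.column_stack(
                [np.concatenate([lb2, np.zeros(n)]),
                 np.concatenate([ub2, np.full(n, amax)])]
            )
            res = linprog(
                self._p_c,
                A_eq=self._p_A_eq,
                b_eq=np.zeros(self._p_A_eq.shape[0]),
                A_ub=self._p_A_ub,
                b_ub=self._p_b_ub,
                bounds=bounds,
                method="highs",
                options={"primal_feasibility_tolerance": 1e-10,
                         "dual_feasibility_tolerance": 1e-9},
            )
            if res.status == 0:
                return res.x[:n]
        # numerically stuck: fall back to the plain optimum
        res0 = linprog(
            self.c, A_eq=self.A_eq, b_eq=self.b_eq,
            bounds=np.column_stack([lb, ub]), method="highs",
        )
        return res0.x

    def minmax_flux(
        self,
        rxn_id: str,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
    ) -> tuple[float, float]:
        """Minimise and maximise one reaction flux under the current system."""
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        bounds = np.column_stack([lb, ub])
        j = self.model._rxn_index[rxn_id]
        c = np.zeros(self.n)
        out = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res = linprog(
                c, A_eq=self.A_eq, b_eq=self.b_eq, bounds=bounds, method="highs"
            )
            if res.status != 0:
                raise ModelError(
                    f"LP for flux range of {rxn_id!r} returned status "
                    f"{_STATUS.get(res.status)}"
                )
            out.append(sign * res.fun)
            c[j] = 0.0
        return out[0], out[1]


def solve_fba(
    model: StoichModel,
    extra_constraints: Iterable[RatioConstraint] = (),
) -> FBASolution:
    """Maximise the objective flux subject to ``S v = 0``, bounds and ratio
    equalities.  Returns status faithfully (optimal/infeasible/unbounded)."""
    return CompiledLP(model, extra_constraints).solve(parsimonious=False)


def solve_fba_parsimonious(
    model: StoichModel,
    extra_constraints: Iterable[RatioConstraint] = (),
) -> FBASolution:
    """FBA with the L1-minimal (parsimonious) flux vector at the optimum."""
    return CompiledLP(model, extra_constraints).solve(parsimonious=True)
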