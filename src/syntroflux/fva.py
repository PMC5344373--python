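"""Flux variability analysis at a fixed fraction of the optimum.

For each reaction, the minimum and maximum flux compatible with the
objective held at ``objective_fraction`` times its optimal value is
computed by two LPs.  Zero-width ranges mean the flux is fully determined
by the data/constraints; wide ranges flag alternative intracellular
routes that would fit equally well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import CompiledLP, ModelError, RatioConstraint, StoichModel, FLUX_TOL

__all__ = ["FVAResult", "flux_variability", "count_variable"]

#: reactions with (max - min) above this are counted as variable
DEFAULT_VARIABILITY_TOL = 1e-6


@dataclass
class FVAResult:
    min_flux: dict[str, float]
    max_flux: dict[str, float]
    objective_fraction: float
    objective_value: float = 0.0

    def range_width(self, rxn_id: str) -> float:
        return self.max_flux[rxn_id] - self.min_flux[rxn_id]

    def to_frame(self, tol: float = DEFAULT_VARIABILITY_TOL) -> pd.DataFrame:
        rows = [
            {
                "reaction": r,
                "min": self.min_flux[r],
                "max": self.max_flux[r],
                "width": self.max_flux[r] - self.min_flux[r],
                "variable": (self.max_flux[r] - self.min_flux[r]) > tol,
            }
            for r in self.min_flux
        ]
        return pd.DataFrame(rows)


def flux_variability(
    model: StoichModel,
    constraints: Iterable[RatioConstraint] = (),
    objective_fraction: float = 1.0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FVAResult:
    """Per-reaction flux ranges with the objective fixed at a fraction of
    its optimum.

    ``bounds`` optionally overrides reaction bounds (e.g. kinetic uptake
    caps at the fitted state).  If fixing the objective renders the LP
    infeasible numerically, the floor is retried with a small slack before
    giving up.
    """
    if not (0.0 < objective_fraction <= 1.0):
        raise ValueError("objective_fraction must be in (0, 1]")
    lp = CompiledLP(model, constraints)
    lb = lp.lb.copy()
    ub = lp.ub.copy()
    if bounds:
        idx = model._rxn_index
        for rxn_id, (lo, hi) in bounds.items():
            j = idx[rxn_id]
            lb[j], ub[j] = lo, hi
    sol = lp.solve(lb, ub, parsimonious=False)
    if sol.status != "optimal":
        raise ModelError(f"FBA not optimal before FVA: status {sol.status}")
    opt = sol.objective_value

    floor = objective_fraction * opt
    for slack in (0.0, FLUX_TOL):
        lb2 = lb.copy()
        lb2[lp.obj_idx] = max(lb[lp.obj_idx], floor - slack)
        try:
            mins, maxs = {}, {}
            for rxn in model.reactions:
                lo, hi = lp.minmax_flux(rxn.id, lb2, ub)
                if abs(lo) < FLUX_TOL:
                    lo = 0.0
                if abs(hi) < FLUX_TOL:
                    hi = 0.0
                mins[rxn.id], maxs[rxn.id] = lo, hi
            return FVAResult(
                min_flux=mins, max_flux=maxs,
                objective_fraction=objective_fraction, objective_value=opt,
            )
        except ModelError:
            if slack > 0.0:
                raise
    raise ModelError("FVA infeasible even with slack")  # pragma: no cover


def count_variable(
    res: FVAResult, tol: float = DEFAULT_VARIABILITY_TOL
) -> tuple[int, float]:
    """Number and fraction of reactions whose flux range exceeds ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = sum(
        1 for r in res.min_flux if (res.max_flux[r] - res.min_flux[r]) > tol
    )
    return n, n / len(res.min_flux)
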