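"""Independent oracles for the test suite.

Brute-force vertex enumeration of the FBA polytope {v : S v = 0,
lb <= v <= ub}: every vertex has at least n - rank(S) coordinates at a
bound, so enumerating bound patterns over coordinate subsets and solving
the remaining square-ish system visits every vertex.  Practical only for
tiny networks (n <= 6), which is exactly what makes it independent of
the LP solver it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from syntroflux.core import Metabolite, Reaction, build_model


def enumerate_vertices(A: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> list[np.ndarray]:
    A = np.asarray(A, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = A.shape
    r = np.linalg.matrix_rank(A) if A.size else 0
    n_fixed = n - r
    verts: list[np.ndarray] = []
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        B = A[:, free]
        if free and np.linalg.matrix_rank(B) < len(free):
            continue
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -A[:, list(fixed)] @ np.array(vals) if fixed else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            else:
                sol = np.array([])
            v = np.empty(n)
            v[list(fixed)] = vals
            v[free] = sol
            if np.max(np.abs(A @ v), initial=0.0) > 1e-7:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                verts.append(np.clip(v, lb, ub))
    return verts


def brute_force_fba(model, extra_rows: np.ndarray | None = None):
    """(max objective, list of optimal vertices) by enumeration."""
    A = model.matrix
    if extra_rows is not None and len(extra_rows):
        A = np.vstack([A, extra_rows])
    lb, ub = model.bounds_arrays()
    verts = enumerate_vertices(A, lb, ub)
    if not verts:
        return None, []
    j = model.reaction_ids.index(model.objective_id)
    best = max(v[j] for v in verts)
    opt = [v for v in verts if v[j] >= best - 1e-9]
    return best, opt


def brute_force_fva(model):
    """Per-reaction (min, max) over the optimal face, by enumeration.

    At objective fraction 1 the optimal face is a face of the polytope,
    so its vertices are polytope vertices and coordinate-wise extremes
    over the optimal vertices give the exact FVA ranges.
    """
    best, opt = brute_force_fba(model)
    ranges = {}
    for j, rid in enumerate(model.reaction_ids):
        ranges[rid] = (min(v[j] for v in opt), max(v[j] for v in opt))
    return best, ranges


def random_toy_model(rng: np.random.Generator):
    """Random small, well-conditioned network: integer stoichiometry,
    integer bounds, objective on reaction 0.  v = 0 is always feasible,
    bounds are finite, so LP and enumeration are always comparable."""
    n = int(rng.integers(3, 7))  # reactions
    m = int(rng.integers(1, max(2, n - 1)))  # internal metabolites
    S = np.zeros((m, n))
    while np.any(np.all(S == 0, axis=1)):
        S = rng.choice([-2, -1, 0, 1, 2], size=(m, n),
                       p=[0.1, 0.3, 0.2, 0.3, 0.1]).astype(float)
    mets = [Metabolite(f"m{i}") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}": S[i, j] for i in range(m) if S[i, j] != 0}
        if not stoich:
            stoich = {"m0": 1.0}
            S[0, j] = 1.0
        lo = float(rng.choice([0.0, -float(rng.integers(1, 5))]))
        hi = float(rng.integers(1, 6))
        rxns.append(Reaction(f"r{j}", stoich, lo, hi))
    return build_model(mets, rxns, "r0")
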