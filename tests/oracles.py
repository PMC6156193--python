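"""Independent oracles used by the test suite.

The vertex-enumeration LP solver below never touches the package's solver
path: it enumerates candidate basic feasible points of the flux polytope
``{v : S v = 0, lb <= v <= ub}`` directly (all bounds finite, so the
polytope is bounded and any feasible LP attains its optimum at a vertex)
and takes the best objective value by brute force.  Only practical for a
handful of reactions, which is the point.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from symbioflux import MetabolicModel, Metabolite, Reaction


def brute_force_lp(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray,
                   tol: float = 1e-9):
    """(status, optimum) for max c.v s.t. S v = 0, lb <= v <= ub.

    Enumerates vertices: fix n - rank(S) variables at a bound, solve the
    equality system for the rest, keep feasible solutions.
    """
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    best = None
    for fixed_tuple in combinations(range(n), n_fixed):
        fixed = list(fixed_tuple)
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # underdetermined: this active set cannot define a vertex
        for choice in product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, pick in zip(fixed, choice):
                v[j] = ub[j] if pick else lb[j]
            rhs = -S[:, fixed] @ v[fixed] if n_fixed else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol * max(1.0, np.max(np.abs(v))):
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    if best is None:
        return "infeasible", float("nan")
    return "optimal", best


def random_small_model(rng: np.random.Generator, max_reactions: int = 8):
    """A random bounded flux model with <= ``max_reactions`` reactions."""
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, min(n, 5) + 1))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    # ensure no empty rows (isolated metabolites make the system trivial)
    for i in range(m):
        if not S[i].any():
            S[i, rng.integers(0, n)] = 1.0
    ub = rng.uniform(0.5, 10.0, size=n).round(3)
    lb = np.where(rng.random(n) < 0.5, -rng.uniform(0.5, 10.0, size=n).round(3), 0.0)
    c = rng.integers(-2, 3, size=n).astype(float)
    if not c.any():
        c[0] = 1.0

    model = MetabolicModel(id="random_lp")
    for i in range(m):
        model.add_metabolite(Metabolite(f"M{i}[c]", compartment_id="c"))
    for j in range(n):
        stoich = {f"M{i}[c]": S[i, j] for i in range(m) if S[i, j]}
        if not stoich:
            stoich = {"M0[c]": 0.0}
        model.add_reaction(
            Reaction(f"R{j}", stoichiometry=stoich,
                     lower_bound=float(lb[j]), upper_bound=float(ub[j]),
                     kind="exchange" if len(stoich) == 1 else "internal")
        )
    model.objective = {f"R{j}": float(c[j]) for j in range(n) if c[j]}
    return model, S, lb, ub, c
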