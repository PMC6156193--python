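"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA solves ``max c·v  s.t.  S·v = 0, lb <= v <= ub`` with the HiGHS linear
programming solver (via :func:`scipy.optimize.linprog`), which is
deterministic for a fixed reaction ordering.  FVA then minimizes and
maximizes each reaction's flux while pinning the objective at (a fraction
of) its optimum, giving the feasible flux range per reaction.

Because LP optima can be degenerate, an optional *stabilized* mode re-solves
for the flux vector of minimum total |v| among alternative optima, making
reported per-reaction fluxes reproducible; plain FBA is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel, build_matrix

__all__ = [
    "FluxSolution",
    "FVAResult",
    "solve_fba",
    "solve_fva",
    "flux_range_summary",
    "transport_flux_variation",
    "FluxRangeSummary",
]

FEASIBILITY_TOL = 1e-9
#: slack used when fixing the objective in FVA / stabilization
def _objective_slack(opt: float) -> float:
    return max(1e-9, 1e-6 * abs(opt))


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    status: str
    objective_value: float
    flux: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.flux[reaction_id]


@dataclass
class FVAResult:
    """Per-reaction feasible flux range at a fixed objective value."""

    ranges: Dict[str, Tuple[float, float]]
    objective_value: float
    objective_fraction: float = 1.0

    def range_width(self, reaction_id: str) -> float:
        lo, hi = self.ranges[reaction_id]
        return hi - lo

    def widths(self) -> Dict[str, float]:
        return {r: hi - lo for r, (lo, hi) in self.ranges.items()}


def _lp_arrays(model: MetabolicModel):
    sm = build_matrix(model)
    n = len(sm.reaction_ids)
    c = np.zeros(n)
    for rid, coeff in model.objective.items():
        c[sm.reaction_ids.index(rid)] = coeff
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in sm.reaction_ids
    ]
    return sm, c, bounds


def _solve(c_min, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c_min,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )


def solve_fba(
    model: MetabolicModel,
    sense: str = "maximize",
    stabilize: bool = False,
) -> FluxSolution:
    """Solve the FBA linear program.

    Infeasible/unbounded models are reported through ``status``, not raised.
    With ``stabilize=True`` a second LP minimizes the total absolute flux
    among alternative optima (objective pinned within its tolerance) so the
    reported flux vector is unique in practice.
    """
    if not model.objective:
        raise ValueError(f"model {model.id!r} has an empty objective")
    if sense not in {"maximize", "minimize"}:
        raise ValueError(f"unknown sense {sense!r}")
    sm, c, bounds = _lp_arrays(model)
    sign = -1.0 if sense == "maximize" else 1.0
    m = sm.matrix.shape[0]
    res = _solve(sign * c, sm.matrix, np.zeros(m), bounds)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x
    obj = float(c @ v)
    if stabilize:
        v = _stabilized_fluxes(sm, c, bounds, obj, sense)
        obj = float(c @ v)
    flux = {rid: float(x) for rid, x in zip(sm.reaction_ids, v)}
    return FluxSolution(status="optimal", objective_value=obj, flux=flux)


def _stabilized_fluxes(sm, c, bounds, opt: float, sense: str) -> np.ndarray:
    """min Σ t_i  s.t.  S v = 0, c·v pinned at opt, -t <= v <= t."""
    n = sm.matrix.shape[1]
    m = sm.matrix.shape[0]
    A_eq = sparse.hstack([sm.matrix, sparse.csc_matrix((m, n))]).tocsc()
    b_eq = np.zeros(m)
    eye = sparse.identity(n, format="csc")
    slack = _objective_slack(opt)
    if sense == "maximize":
        obj_row = sparse.hstack([sparse.csr_matrix(-c), sparse.csr_matrix((1, n))])
        obj_rhs = [-(opt - slack)]
    else:
        obj_row = sparse.hstack([sparse.csr_matrix(c), sparse.csr_matrix((1, n))])
        obj_rhs = [opt + slack]
    A_ub = sparse.vstack([
        obj_row,
        sparse.hstack([eye, -eye]),    # v - t <= 0
        sparse.hstack([-eye, -eye]),   # -v - t <= 0
    ]).tocsc()
    b_ub = np.concatenate([obj_rhs, np.zeros(2 * n)])
    big = max(abs(lo) if np.isfinite(lo) else 0 for lo, _ in bounds)
    big = max(big, max(abs(hi) if np.isfinite(hi) else 0 for _, hi in bounds))
    t_bounds = [(0.0, big) for _ in range(n)]
    c_min = np.concatenate([np.zeros(n), np.ones(n)])
    res = _solve(c_min, A_eq, b_eq, list(bounds) + t_bounds, A_ub=A_ub, b_ub=b_ub)
    if res.status != 0:
        raise RuntimeError(f"flux stabilization LP failed: {res.message}")
    return res.x[:n]


def solve_fva(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
) -> FVAResult:
    """Flux variability analysis at a fixed (fraction of the) optimum.

    For each reaction two LPs minimize and maximize its flux subject to the
    original constraints plus ``c·v >= fraction x optimum`` (within the
    numerical slack).  The 2n LPs are independent, so execution order does
    not affect the result.
    """
    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise RuntimeError(
            f"FVA requires an optimal FBA solution; status = {base.status}"
        )
    sm, c, bounds = _lp_arrays(model)
    m = sm.matrix.shape[0]
    target = objective_fraction * base.objective_value
    slack = _objective_slack(base.objective_value)
    A_ub = sparse.csr_matrix(-c)      # -c.v <= -(target - slack)
    b_ub = np.array([-(target - slack)])
    which = list(reactions) if reactions is not None else sm.reaction_ids
    ranges: Dict[str, Tuple[float, float]] = {}
    n = len(sm.reaction_ids)
    idx = {r: i for i, r in enumerate(sm.reaction_ids)}
    for rid in which:
        e = np.zeros(n)
        e[idx[rid]] = 1.0
        lohi = []
        for sgn in (1.0, -1.0):
            res = _solve(sgn * e, sm.matrix, np.zeros(m), bounds, A_ub=A_ub, b_ub=b_ub)
            if res.status != 0:
                raise RuntimeError(
                    f"FVA subproblem for {rid} failed with status "
                    f"{_STATUS.get(res.status, res.status)}"
                )
            lohi.append(float(sgn * res.fun))
        lo, hi = lohi
        if lo > hi:  # numerical jitter on a pinned reaction
            lo, hi = hi, lo
        ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, objective_value=base.objective_value,
                     objective_fraction=objective_fraction)


@dataclass
class FluxRangeSummary:
    """Fraction of reactions whose FVA range is below a threshold."""

    fraction_below: float
    threshold: float
    n_reactions: int
    widths: Dict[str, float]

    def histogram(self, bins: int = 20):
        return np.histogram(list(self.widths.values()), bins=bins)


def flux_range_summary(fva: FVAResult, threshold: float = 1.0) -> FluxRangeSummary:
    """Summarize how tightly the optimum pins the network's fluxes."""
    widths = fva.widths()
    n = len(widths)
    below = sum(1 for w in widths.values() if w < threshold)
    return FluxRangeSummary(
        fraction_below=below / n if n else float("nan"),
        threshold=threshold,
        n_reactions=n,
        widths=widths,
    )


def transport_flux_variation(
    fva: FVAResult,
    sol: FluxSolution,
    transports: Iterable[str],
    zero_tol: float = 1e-9,
) -> Dict[str, Optional[float]]:
    """Percent FVA variation per transport: 100 x (max - min) / |v_opt|.

    Transports with |v_opt| below ``zero_tol`` are reported as ``None``
    ("undefined") and should be excluded from summary fractions.
    """
    if not sol.optimal:
        raise ValueError("transport_flux_variation requires an optimal solution")
    out: Dict[str, Optional[float]] = {}
    for rid in transports:
        v = sol.flux[rid]
        lo, hi = fva.ranges[rid]
        out[rid] = None if abs(v) < zero_tol else 100.0 * (hi - lo) / abs(v)
    return out


def fraction_transports_below(
    variation: Dict[str, Optional[float]], percent: float = 1.0
) -> float:
    """Fraction of defined transport variations under ``percent``."""
    defined = [p for p in variation.values() if p is not None]
    if not defined:
        return float("nan")
    return sum(1 for p in defined if p < percent) / len(defined)
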