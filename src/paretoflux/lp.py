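"""Constraint-based linear programs: FBA, FVA and parsimonious FBA.

All three problems share the steady-state polytope {v : S v = 0,
lb <= v <= ub} and are solved with HiGHS through scipy.optimize.linprog.

* FBA maximizes c^T v over the polytope.
* FVA minimizes/maximizes each single flux subject additionally to
  c^T v >= fraction * (FBA optimum).
* pFBA minimizes sum(|v_i|) subject additionally to c^T v pinned at the
  FBA optimum (an optional relative slack relaxes the pin); absolute
  values use the standard auxiliary-variable reformulation t_i >= |v_i|.

Exchange fluxes follow the usual sign convention: uptake negative,
secretion positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import ModelValidationError, StoichiometricModel

__all__ = ["FluxState", "FluxRange", "SolverSettings", "fba", "fva", "pfba"]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 1: "iteration_limit", 2: INFEASIBLE, 3: UNBOUNDED, 4: "numerical"}


@dataclass(frozen=True)
class SolverSettings:
    """Numerical tolerances forwarded to HiGHS and used in validity checks."""

    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9

    def linprog_options(self) -> dict:
        return {
            "primal_feasibility_tolerance": self.feasibility_tol,
            "dual_feasibility_tolerance": self.optimality_tol,
        }


DEFAULT_SETTINGS = SolverSettings()


@dataclass(frozen=True)
class FluxState:
    """One flux distribution with its objective value and solver status."""

    v: np.ndarray | None
    objective_value: float | None
    status: str
    settings: SolverSettings = DEFAULT_SETTINGS

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, model: StoichiometricModel, reaction_id: str) -> float:
        if self.v is None:
            raise ValueError(f"no flux vector available (status={self.status})")
        return float(self.v[model.reaction_index(reaction_id)])


@dataclass(frozen=True)
class FluxRange:
    """Per-reaction flux intervals from FVA."""

    v_min: np.ndarray
    v_max: np.ndarray
    fraction_of_optimum: float

    def range_of(self, model: StoichiometricModel, reaction_id: str) -> tuple[float, float]:
        j = model.reaction_index(reaction_id)
        return float(self.v_min[j]), float(self.v_max[j])


def _check_model(model: StoichiometricModel) -> None:
    model.validate()
    if not np.any(model.c):
        raise ModelValidationError("degenerate model: all-zero objective vector")


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, settings: SolverSettings):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=settings.linprog_options(),
    )


def fba(
    model: StoichiometricModel, settings: SolverSettings = DEFAULT_SETTINGS
) -> FluxState:
    """Flux balance analysis: maximize c^T v s.t. S v = 0, lb <= v <= ub."""
    _check_model(model)
    res = _solve(
        -model.c,
        None,
        None,
        model.S,
        np.zeros(model.n_metabolites),
        list(zip(model.lb, model.ub)),
        settings,
    )
    status = _STATUS.get(res.status, "error")
    if status != OPTIMAL:
        return FluxState(None, None, status, settings)
    return FluxState(np.asarray(res.x, float), float(-res.fun), OPTIMAL, settings)


def fva(
    model: StoichiometricModel,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> FluxRange:
    """Flux variability analysis at a fraction of the FBA optimum.

    Solves 2 LPs per requested reaction (all reactions by default); for
    unrequested reactions the returned interval is (nan, nan).
    """
    if not (0.0 < fraction_of_optimum <= 1.0):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = fba(model, settings)
    if not base.optimal:
        raise ModelValidationError(f"FVA requires an optimal base FBA, got {base.status}")

    # c^T v >= fraction * opt  as  -c^T v <= -fraction * opt
    A_ub = sp.csr_matrix(-model.c.reshape(1, -1))
    b_ub = np.array([-fraction_of_optimum * base.objective_value])
    bounds = list(zip(model.lb, model.ub))
    b_eq = np.zeros(model.n_metabolites)

    n = model.n_reactions
    idx = (
        range(n)
        if reactions is None
        else [model.reaction_index(r) for r in reactions]
    )
    v_min = np.full(n, np.nan)
    v_max = np.full(n, np.nan)
    for j in idx:
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = _solve(obj, A_ub, b_ub, model.S, b_eq, bounds, settings)
        hi = _solve(-obj, A_ub, b_ub, model.S, b_eq, bounds, settings)
        if lo.status != 0 or hi.status != 0:
            raise ModelValidationError(
                f"FVA subproblem failed for reaction {model.reaction_ids[j]!r}"
            )
        v_min[j] = lo.fun
        v_max[j] = -hi.fun
        if v_min[j] > v_max[j]:  # numerical jitter
            v_min[j] = v_max[j] = 0.5 * (v_min[j] + v_max[j])
    return FluxRange(v_min, v_max, fraction_of_optimum)


def pfba(
    model: StoichiometricModel,
    relative_slack: float = 0.0,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> FluxState:
    """Parsimonious FBA: minimize total absolute flux at the FBA optimum.

    ``relative_slack`` relaxes the growth pin to
    c^T v >= (1 - slack) * optimum; the default 0 enforces equality.
    The reported ``objective_value`` is c^T v of the parsimonious solution
    (i.e. the growth objective, not the flux sum).
    """
    base = fba(model, settings)
    if not base.optimal:
        return base
    opt = base.objective_value

    n = model.n_reactions
    # variables [v (n) ; t (n)], minimize sum t, with t_i >= |v_i|
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sp.hstack([model.S, sp.csr_matrix((model.n_metabolites, n))]).tocsr()
    b_eq = np.zeros(model.n_metabolites)

    eye = sp.identity(n)
    rows = [sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]
    b_ub = [np.zeros(2 * n)]
    if relative_slack == 0.0:
        A_eq = sp.vstack(
            [A_eq, sp.hstack([sp.csr_matrix(model.c.reshape(1, -1)), sp.csr_matrix((1, n))])]
        ).tocsr()
        b_eq = np.concatenate([b_eq, [opt]])
    else:
        rows.append(
            sp.hstack([sp.csr_matrix(-model.c.reshape(1, -1)), sp.csr_matrix((1, n))])
        )
        b_ub.append(np.array([-(1.0 - relative_slack) * opt]))
    A_ub = sp.vstack(rows).tocsr()
    b_ub_arr = np.concatenate(b_ub)

    t_hi = np.maximum(np.abs(model.lb), np.abs(model.ub))
    bounds = list(zip(model.lb, model.ub)) + list(zip(np.zeros(n), t_hi))
    res = _solve(cost, A_ub, b_ub_arr, A_eq, b_eq, bounds, settings)
    status = _STATUS.get(res.status, "error")
    if status != OPTIMAL:
        return FluxState(None, None, status, settings)
    v = np.asarray(res.x[:n], float)
    return FluxState(v, float(model.c @ v), OPTIMAL, settings)
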