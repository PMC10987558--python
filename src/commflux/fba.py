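"""Flux balance analysis by linear programming.

Solves {opt c·v : S·v = 0, lb <= v <= ub} with the HiGHS solver behind
:func:`scipy.optimize.linprog`.  Optimal bases of an FBA problem are
typically degenerate, so after optimizing the primary objective a
parsimonious secondary step minimizes the total absolute flux at the fixed
optimum; the returned flux vector is then deterministic for a given model
and tolerance settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

#: steady-state residual tolerance recorded with every solution
MASS_BALANCE_TOL = 1e-6
#: tolerance by which the parsimonious step may relax the primary optimum
OBJECTIVE_LOCK_TOL = 1e-9


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    fluxes: dict[str, float]
    objective_value: float | None
    tolerances: dict[str, float] = field(
        default_factory=lambda: {
            "mass_balance": MASS_BALANCE_TOL,
            "objective_lock": OBJECTIVE_LOCK_TOL,
        }
    )


def build_stoichiometry(model) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense S (metabolites × reactions) plus row/column orderings."""
    mets = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(mets)}
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoich.items():
            S[met_index[met], j] = coef
    return S, mets, rxns


def fba(model, direction: str = "max", parsimonious: bool = True) -> FluxSolution:
    """Optimize the model objective; optionally resolve degeneracy (pFBA).

    ``direction`` chooses maximization or minimization of the objective
    c·v.  Infeasible and unbounded problems are reported in ``status`` with
    no fluxes.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    S, _, rxn_ids = build_stoichiometry(model)
    n = len(rxn_ids)
    c = np.array([r.objective for r in model.reactions], dtype=float)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    sign = -1.0 if direction == "max" else 1.0

    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxSolution("infeasible", {}, None)
    if res.status == 3:
        return FluxSolution("unbounded", {}, None)
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    obj = float(c @ res.x)
    v = res.x

    if parsimonious and n > 0:
        # min sum t  s.t.  S v = 0,  ±v - t <= 0,  objective locked at obj
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([S, np.zeros_like(S)])
        b_eq = np.zeros(S.shape[0])
        eye = np.eye(n)
        A_ub = np.vstack(
            [
                np.hstack([eye, -eye]),
                np.hstack([-eye, -eye]),
                np.concatenate([sign * c, np.zeros(n)])[None, :],
            ]
        )
        b_ub = np.concatenate(
            [np.zeros(2 * n), [sign * obj + OBJECTIVE_LOCK_TOL]]
        )
        bounds2 = bounds + [(0, None)] * n
        res2 = linprog(
            c2, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
            bounds=bounds2, method="highs",
        )
        if res2.status == 0:
            v = res2.x[:n]
            obj = float(c @ v)

    residual = np.abs(S @ v).max() if S.size else 0.0
    if residual > MASS_BALANCE_TOL:
        raise RuntimeError(
            f"solution violates steady state (|S v|inf = {residual:.2e})"
        )
    return FluxSolution("optimal", dict(zip(rxn_ids, v)), obj)
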