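"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the FBA oracle
enumerates polytope vertices instead of calling an LP solver, the
Bray-Curtis oracle evaluates the formula pairwise, and the AUC oracle
counts concordant case/control pairs.
"""

from __future__ import annotations

import itertools

import numpy as np

from commflux.fba import build_stoichiometry


def vertex_enumeration_fba(model, direction: str = "max") -> float:
    """Optimal objective of {opt c.v : S v = 0, l <= v <= u} by enumerating
    candidate vertices (every choice of n - rank(S) variables at a bound)."""
    S, _, _ = build_stoichiometry(model)
    n = len(model.reactions)
    c = np.array([r.objective for r in model.reactions])
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    r = np.linalg.matrix_rank(S) if S.size else 0
    k = n - r
    best = None
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        Sf = S[:, free]
        for corners in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            v[list(fixed)] = corners
            rhs = -S[:, list(fixed)] @ np.asarray(corners)
            if free:
                sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                v[free] = sol
            if np.abs(S @ v).max() > 1e-7:
                continue
            if (v < lb - 1e-9).any() or (v > ub + 1e-9).any():
                continue
            obj = float(c @ v)
            if best is None:
                best = obj
            elif direction == "max":
                best = max(best, obj)
            else:
                best = min(best, obj)
    if best is None:
        raise RuntimeError("no feasible vertex found")
    return best


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def auc_pair_counting(scores: np.ndarray, y: np.ndarray) -> float:
    """(concordant + 0.5 tied) / (n_pos * n_neg) over all case/control pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def check_steady_state(model, solution, tol: float = 1e-6) -> float:
    """Max |S v| residual of a solution; also checks bounds."""
    S, _, rxn_ids = build_stoichiometry(model)
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    assert (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all(), "bounds violated"
    residual = float(np.abs(S @ v).max()) if S.size else 0.0
    assert residual <= tol, f"steady state violated: {residual}"
    return residual


def random_toy_model(rng: np.random.Generator, n_reactions: int = 6):
    """Random bounded toy model, always feasible (0 in every bound interval)."""
    from commflux.models import MetabolicReconstruction, Reaction

    n_mets = rng.integers(2, max(3, n_reactions - 1))
    mets = {f"m{i}": ("extracellular" if i == 0 else "internal") for i in range(n_mets)}
    rxns = []
    for j in range(n_reactions):
        size = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=size, replace=False)
        stoich = {f"m{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen}
        lb = float(-rng.integers(0, 11))
        ub = float(rng.integers(1, 11))
        rxns.append(Reaction(f"r{j}", stoich, lb, ub, objective=float(rng.normal())))
    return MetabolicReconstruction("toy", mets, rxns)
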