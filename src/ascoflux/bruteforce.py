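"""Brute-force reference solvers for tiny flux polytopes.

These enumerate candidate active sets exhaustively — every assignment of
each reaction to {at lower bound, at upper bound, free} — and are therefore
exponential in the reaction count: they are usable only for networks of a
handful of reactions. They share no code with :mod:`ascoflux.fba` or
:mod:`ascoflux.moma` and exist solely as independent cross-checks of those
solvers' results at desk scale.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .model import MetabolicModel

__all__ = ["brute_force_lp_max", "brute_force_projection", "brute_force_fba"]

_FEAS_TOL = 1e-8


def _patterns(n: int):
    yield from product((0, 1, 2), repeat=n)  # 0 free, 1 lower, 2 upper


def brute_force_lp_max(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray
) -> float | None:
    """Max of c.v over {S.v = 0, lb <= v <= ub} by vertex enumeration.

    All bounds must be finite (bounded polytope). Returns None when the
    polytope is empty. Works by enumerating active-set patterns: fixing the
    active variables at their bounds and solving the remaining square-ish
    system; every vertex (basic feasible solution) appears among the
    patterns, and a bounded LP attains its maximum at a vertex.
    """
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration requires finite bounds")
    n = S.shape[1]
    best: float | None = None
    for pattern in _patterns(n):
        v = _candidate(S, lb, ub, np.array(pattern))
        if v is None:
            continue
        value = float(c @ v)
        if best is None or value > best:
            best = value
    return best


def brute_force_projection(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, float] | None:
    """argmin ||v - r||^2 over {S.v = 0, lb <= v <= ub} by active-set search.

    Enumerates every bound-activity pattern, solves the corresponding
    equality-constrained least-distance problem via its KKT system, keeps
    feasible candidates, and returns the best. The optimum's own active set
    is among the enumerated patterns, so the minimum over feasible
    candidates is the global minimum. Returns None when infeasible.
    """
    n = S.shape[1]
    best_v: np.ndarray | None = None
    best_d = np.inf
    for pattern in _patterns(n):
        v = _candidate_projection(S, lb, ub, r, np.array(pattern))
        if v is None:
            continue
        d = float(np.sum((v - r) ** 2))
        if d < best_d - 1e-15 or best_v is None:
            best_v, best_d = v, d
    if best_v is None:
        return None
    return best_v, best_d


def brute_force_fba(model: MetabolicModel) -> float | None:
    """Vertex-enumeration FBA maximum for a tiny model."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(model.objective.id)] = 1.0
    return brute_force_lp_max(S, lb, ub, c)


def _fixed_values(
    lb: np.ndarray, ub: np.ndarray, pattern: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    fixed = pattern > 0
    values = np.where(pattern == 1, lb, ub)
    if np.any(~np.isfinite(values[fixed])):
        return None
    return fixed, values


def _candidate(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, pattern: np.ndarray
) -> np.ndarray | None:
    out = _fixed_values(lb, ub, pattern)
    if out is None:
        return None
    fixed, values = out
    free = ~fixed
    v = np.where(fixed, values, 0.0)
    if free.any():
        S_free = S[:, free]
        b = -S[:, fixed] @ values[fixed] if fixed.any() else np.zeros(S.shape[0])
        if np.linalg.matrix_rank(S_free) < int(free.sum()):
            return None  # not a vertex: free part under-determined
        sol, *_ = np.linalg.lstsq(S_free, b, rcond=None)
        if np.max(np.abs(S_free @ sol - b), initial=0.0) > _FEAS_TOL:
            return None
        v[free] = sol
    if np.max(np.abs(S @ v), initial=0.0) > _FEAS_TOL:
        return None
    if np.any(v < lb - _FEAS_TOL) or np.any(v > ub + _FEAS_TOL):
        return None
    return v


def _candidate_projection(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, r: np.ndarray, pattern: np.ndarray
) -> np.ndarray | None:
    out = _fixed_values(lb, ub, pattern)
    if out is None:
        return None
    fixed, values = out
    free = ~fixed
    v = np.where(fixed, values, 0.0)
    m = S.shape[0]
    if free.any():
        S_free = S[:, free]
        b = -S[:, fixed] @ values[fixed] if fixed.any() else np.zeros(m)
        nf = int(free.sum())
        K = np.block([[np.eye(nf), S_free.T], [S_free, np.zeros((m, m))]])
        rhs = np.concatenate([r[free], b])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        if np.max(np.abs(K @ sol - rhs), initial=0.0) > _FEAS_TOL * max(
            1.0, float(np.max(np.abs(rhs), initial=0.0))
        ):
            return None
        v[free] = sol[:nf]
    if np.max(np.abs(S @ v), initial=0.0) > _FEAS_TOL:
        return None
    if np.any(v < lb - _FEAS_TOL) or np.any(v > ub + _FEAS_TOL):
        return None
    return v
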