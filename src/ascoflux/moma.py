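"""Minimization of metabolic adjustment (MOMA).

After a perturbation (here: forcing an amplified flux through one reaction)
the cell is assumed to redistribute flux as little as possible rather than
re-optimize growth. That hypothesis is the quadratic program

    minimize   sum_i (v_i - v_ref,i)^2
    subject to S.v = 0,  lb <= v <= ub  (+ perturbation bound edits)

i.e. the Euclidean projection of the wild-type reference onto the perturbed
flux polytope. The QP is solved with OSQP and then polished exactly: the
active bounds identified by the solver are fixed, the equality-constrained
projection is solved by a dense KKT least-squares system, and the polished
point is accepted only if it is primal and dual feasible. This brings the
steady-state residual to machine precision, which the raw first-order
iterates of ADMM-style solvers do not guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .builder import BoundEdit
from .fba import FluxDistribution, SolverError, _apply_extra_bounds
from .model import MetabolicModel

__all__ = ["MomaSolution", "moma"]

#: residual tolerance on QP optimality (OSQP eps_abs/eps_rel)
QP_TOL = 1e-8
#: tolerance used when classifying a bound as active for polishing
ACTIVE_TOL = 1e-6


@dataclass
class MomaSolution:
    """Perturbed flux distribution closest to the reference."""

    fluxes: dict[str, float]
    distance_sq: float
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def moma(
    model: MetabolicModel,
    reference: FluxDistribution,
    perturbation: list[BoundEdit] | None = None,
    weights: dict[str, float] | None = None,
) -> MomaSolution:
    """Project the reference onto the perturbed flux polytope.

    ``weights`` is a hook for a weighted Euclidean distance; the default
    (all ones) is the canonical MOMA objective. Infeasible perturbations are
    reported through ``status``, not raised, so a target scan can skip them.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    missing = [r for r in rxn_ids if r not in reference.fluxes]
    if missing:
        raise KeyError(f"reference does not cover reactions: {missing[:5]}")
    lb, ub = model.bounds_arrays(rxn_ids)
    _apply_extra_bounds(lb, ub, rxn_ids, perturbation)
    if np.any(lb > ub + 1e-12):
        return MomaSolution(fluxes={}, distance_sq=float("nan"), status="infeasible")
    r = np.array([reference.fluxes[rid] for rid in rxn_ids])
    w = np.ones(len(rxn_ids))
    if weights:
        for i, rid in enumerate(rxn_ids):
            w[i] = weights.get(rid, 1.0)

    v, status = _solve_qp(S, lb, ub, r, w)
    if status != "optimal":
        return MomaSolution(fluxes={}, distance_sq=float("nan"), status="infeasible")
    dist = float(np.sum(w * (v - r) ** 2))
    return MomaSolution(
        fluxes=dict(zip(rxn_ids, (float(x) for x in v))),
        distance_sq=dist,
        status="optimal",
    )


def _solve_qp(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, r: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray | None, str]:
    import osqp

    m, n = S.shape
    P = sp.diags(2.0 * w, format="csc")
    q = -2.0 * w * r
    A = sp.vstack([sp.csc_matrix(S), sp.identity(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(m), lb])
    u = np.concatenate([np.zeros(m), ub])
    solver = osqp.OSQP()
    solver.setup(
        P=P,
        q=q,
        A=A,
        l=l,
        u=u,
        verbose=False,
        eps_abs=QP_TOL,
        eps_rel=QP_TOL,
        eps_prim_inf=1e-9,
        eps_dual_inf=1e-9,
        max_iter=200_000,
        polishing=True,
    )
    result = solver.solve(raise_error=False)
    status = result.info.status
    if "infeasible" in status:
        return None, "infeasible"
    hit_iter_cap = "maximum iterations" in status
    if "solved" not in status and not hit_iter_cap:
        raise SolverError(f"QP solver failure: {status}")
    v = np.asarray(result.x, dtype=float)
    polished = _kkt_polish(S, lb, ub, r, w, v)
    if polished is None:
        # first-order iterate too far from the optimum to reveal the active
        # set; refine through the smooth concave dual of the projection
        refined = _dual_refine(S, lb, ub, r, w, np.asarray(result.y, dtype=float)[: S.shape[0]])
        if refined is not None:
            polished = _kkt_polish(S, lb, ub, r, w, refined)
            if polished is None and _feasible_enough(S, lb, ub, refined):
                polished = refined
    if polished is not None:
        v = polished
    elif hit_iter_cap:
        raise SolverError(f"QP solver failure: {status}")
    return v, "optimal"


def _feasible_enough(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, v: np.ndarray) -> bool:
    return (
        np.max(np.abs(S @ v), initial=0.0) <= 1e-7
        and not np.any(v < lb - 1e-9)
        and not np.any(v > ub + 1e-9)
    )


def _dual_refine(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    y0: np.ndarray,
) -> np.ndarray | None:
    """High-accuracy primal point via the dual of the projection problem.

    For min ½ sum w_i (v_i - r_i)^2 s.t. S.v = 0, lb <= v <= ub, the dual in
    the steady-state multipliers y is smooth and concave with

        v*(y) = clip(r - S'y / w, lb, ub),   grad g(y) = S v*(y)

    and is maximized here with L-BFGS-B; the clipping pattern of v*(y) at
    the dual optimum identifies the true active set.
    """
    from scipy.optimize import minimize

    def neg_dual(y: np.ndarray) -> tuple[float, np.ndarray]:
        v = np.clip(r - (S.T @ y) / w, lb, ub)
        g = 0.5 * float(np.sum(w * (v - r) ** 2)) + float(y @ (S @ v))
        return -g, -(S @ v)

    res = minimize(
        neg_dual,
        y0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-12},
    )
    if not np.all(np.isfinite(res.x)):
        return None
    return np.clip(r - (S.T @ res.x) / w, lb, ub)


def _kkt_polish(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    v: np.ndarray,
) -> np.ndarray | None:
    """Exact projection given the active set identified by the QP solver.

    Fix variables at bounds the iterate touches, solve the free-variable
    projection from the KKT system, and verify primal feasibility and the
    sign of the bound multipliers. Returns None when the guess fails, in
    which case the caller keeps the solver's iterate.
    """
    n = len(v)
    at_lower = np.isfinite(lb) & (v - lb <= ACTIVE_TOL)
    at_upper = np.isfinite(ub) & (ub - v <= ACTIVE_TOL) & ~at_lower
    free = ~(at_lower | at_upper)
    fixed_v = np.where(at_lower, lb, np.where(at_upper, ub, 0.0))

    x = np.array(fixed_v)
    W = np.diag(w)
    if free.any():
        S_free = S[:, free]
        b = -S[:, ~free] @ fixed_v[~free] if (~free).any() else np.zeros(S.shape[0])
        # minimize (v_F - r_F)' W_F (v_F - r_F)  s.t.  S_F v_F = b
        # KKT: W_F v_F + S_F' y = W_F r_F ; S_F v_F = b
        nf = int(free.sum())
        W_f = W[np.ix_(free, free)]
        K = np.block(
            [[2.0 * W_f, S_free.T], [S_free, np.zeros((S.shape[0], S.shape[0]))]]
        )
        rhs = np.concatenate([2.0 * w[free] * r[free], b])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        v_free, y = sol[:nf], sol[nf:]
        # the KKT system must actually be solved (it can be inconsistent
        # when the active-set guess makes S_F v_F = b infeasible)
        if np.max(np.abs(K @ sol - rhs)) > 1e-7 * max(1.0, np.max(np.abs(rhs))):
            return None
        x[free] = v_free
    else:
        # all variables fixed: recover multipliers for the dual check
        y, *_ = np.linalg.lstsq(S.T, 2.0 * w * (r - x), rcond=None)

    if np.max(np.abs(S @ x)) > 1e-8 * max(1.0, float(np.max(np.abs(x))), 1.0):
        return None
    if np.any(x < lb - 1e-9) or np.any(x > ub + 1e-9):
        return None
    if not free.any():
        grad = 2.0 * w * (x - r) + S.T @ y
    else:
        grad = 2.0 * w * (x - r) + S.T @ y
    scale = max(1.0, float(np.max(np.abs(grad))))
    # dual feasibility: gradient must push against the active bound
    if np.any(grad[at_lower] < -1e-6 * scale) or np.any(grad[at_upper] > 1e-6 * scale):
        return None
    if free.any() and np.max(np.abs(grad[free])) > 1e-6 * scale:
        return None
    return x
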