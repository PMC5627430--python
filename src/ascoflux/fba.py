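"""Flux balance analysis: maximize an objective flux over {S.v = 0, lb <= v <= ub}.

The LP is solved with HiGHS through :func:`scipy.optimize.linprog`. Because
FBA optima are routinely degenerate and the downstream MOMA step needs one
reproducible reference vector, :func:`reference_flux` fixes the objective at
its optimum and then minimizes total absolute flux (the parsimonious
secondary objective); LP columns are assembled in lexicographic reaction-id
order so the whole solve is a deterministic function of model content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .builder import BoundEdit
from .model import MetabolicModel

__all__ = ["FluxDistribution", "SolverError", "fba", "reference_flux", "fix_flux"]

#: |S.v| feasibility tolerance for an optimal distribution
STEADY_STATE_TOL = 1e-6
#: bound-violation tolerance
BOUND_TOL = 1e-9


class SolverError(RuntimeError):
    """LP backend failed for a reason other than infeasibility/unboundedness."""


@dataclass
class FluxDistribution:
    """One flux value per reaction, with solver status.

    All fluxes are mmol.gDCW^-1.h^-1 except the biomass flux (h^-1).
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def fix_flux(rxn_id: str, value: float) -> list[BoundEdit]:
    """Convenience: bound edits pinning one flux to an exact value."""
    return [BoundEdit(rxn_id, "lower", value), BoundEdit(rxn_id, "upper", value)]


def _apply_extra_bounds(
    lb: np.ndarray, ub: np.ndarray, rxn_ids: list[str], extra: list[BoundEdit] | None
) -> None:
    if not extra:
        return
    index = {r: i for i, r in enumerate(rxn_ids)}
    for edit in extra:
        if edit.reaction_id not in index:
            raise KeyError(f"bound edit references unknown reaction {edit.reaction_id!r}")
        i = index[edit.reaction_id]
        if edit.which == "lower":
            lb[i] = edit.value
        else:
            ub[i] = edit.value


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def fba(
    model: MetabolicModel, extra_bounds: list[BoundEdit] | None = None
) -> FluxDistribution:
    """Maximize the objective flux; statuses infeasible/unbounded are data,
    any other solver failure raises :class:`SolverError` with the log."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    _apply_extra_bounds(lb, ub, rxn_ids, extra_bounds)
    obj_idx = rxn_ids.index(model.objective.id)
    c = np.zeros(len(rxn_ids))
    c[obj_idx] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failure (status {res.status}): {res.message}")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status=status)
    fluxes = dict(zip(rxn_ids, (float(x) for x in res.x)))
    return FluxDistribution(fluxes=fluxes, objective_value=float(res.x[obj_idx]), status="optimal")


def reference_flux(
    model: MetabolicModel, extra_bounds: list[BoundEdit] | None = None
) -> FluxDistribution:
    """FBA optimum with minimum total absolute flux (parsimonious reference).

    Solves max objective, then min sum_i |v_i| subject to the objective flux
    being held at its optimum; the auxiliary LP uses split variables
    v = p - n with p, n >= 0, which makes the L1 objective linear.
    """
    first = fba(model, extra_bounds)
    if not first.optimal:
        return first
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    _apply_extra_bounds(lb, ub, rxn_ids, extra_bounds)
    obj_idx = rxn_ids.index(model.objective.id)
    # pin the objective at its optimum
    lb[obj_idx] = ub[obj_idx] = first.objective_value
    n = len(rxn_ids)
    m = S.shape[0]
    # variables [p; q]: v = p - q, p in [0, max(ub,0)], q in [0, max(-lb,0)]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    # enforce lb <= p - q <= ub through linear inequality rows where needed
    A_ub_rows = []
    b_ub_rows = []
    for i in range(n):
        #  p_i - q_i <= ub_i and -(p_i - q_i) <= -lb_i
        row = np.zeros(2 * n)
        row[i], row[n + i] = 1.0, -1.0
        A_ub_rows.append(row)
        b_ub_rows.append(ub[i])
        A_ub_rows.append(-row)
        b_ub_rows.append(-lb[i])
    bounds = [(0.0, max(ub[i], 0.0)) for i in range(n)] + [
        (0.0, max(-lb[i], 0.0)) for i in range(n)
    ]
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=np.array(A_ub_rows),
        b_ub=np.array(b_ub_rows),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        # degenerate numerical corner: fall back to the raw FBA solution
        return first
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, (float(x) for x in v)))
    return FluxDistribution(
        fluxes=fluxes, objective_value=first.objective_value, status="optimal"
    )


def check_distribution(
    model: MetabolicModel,
    dist: FluxDistribution,
    extra_bounds: list[BoundEdit] | None = None,
) -> tuple[float, float]:
    """(max |S.v| residual, max bound violation) for a distribution; test aid."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    _apply_extra_bounds(lb, ub, rxn_ids, extra_bounds)
    v = np.array([dist.fluxes[r] for r in rxn_ids])
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    violation = float(np.max(np.maximum(lb - v, v - ub)))
    return residual, max(violation, 0.0)
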