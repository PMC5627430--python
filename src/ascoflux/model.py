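"""Constraint-based metabolic model containers.

A :class:`MetabolicModel` is the universe every solver in this package
operates on: a set of metabolites, a set of reactions with stoichiometry and
flux bounds, one designated biomass (objective) reaction whose flux is the
specific growth rate (h^-1), and optionally one designated product reaction
(here: the ascomycin synthesis/export flux). All other fluxes are in
mmol.gDCW^-1.h^-1. Steady state means S.v = 0 where S has one row per
metabolite and one column per reaction.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationReport",
    "ModelValidationError",
    "validate_model",
    "parse_formula",
]

#: default flux-bound magnitude, mmol.gDCW^-1.h^-1
DEFAULT_BOUND = 1000.0

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """Raised when a model or one of its elements violates an invariant."""


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be non-empty"
            )


@dataclass
class Reaction:
    """A (pseudo-)reaction: signed stoichiometry plus flux bounds.

    Negative stoichiometric coefficients are substrates, positive products.
    Exchange/sink pseudo-reactions have a single metabolite; the biomass
    pseudo-reaction drains precursors in growth proportions.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    @property
    def boundary(self) -> bool:
        """True for exchange/sink/demand pseudo-reactions (one metabolite)."""
        return len(self.stoichiometry) == 1


class MetabolicModel:
    """Metabolites + reactions + objective, with S.v = 0 semantics."""

    def __init__(
        self,
        id: str = "model",
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        objective_id: str | None = None,
        product_id: str | None = None,
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id = objective_id
        self.product_id = product_id
        for met in metabolites or []:
            self.add_metabolite(met)
        for rxn in reactions or []:
            self.add_reaction(rxn)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, allow_new_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                if allow_new_metabolites:
                    self.add_metabolite(Metabolite(id=mid, compartment=_compartment_of(mid)))
                else:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- views -------------------------------------------------------------

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None or self.objective_id not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} not in model"
            )
        return self.reactions[self.objective_id]

    def stoichiometric_matrix(
        self,
    ) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus its row and column ids.

        Columns are ordered by lexicographic reaction id, rows by metabolite
        id, so the matrix is a canonical function of model content.
        """
        met_ids = sorted(self.metabolites)
        rxn_ids = sorted(self.reactions)
        row = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[row[mid], j] = coef
        return S, met_ids, rxn_ids

    def bounds_arrays(self, rxn_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([self.reactions[r].upper_bound for r in rxn_ids])
        return lb, ub

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, objective={self.objective_id}>"
        )


def _compartment_of(met_id: str) -> str:
    """Compartment from a trailing _<token> suffix; cytosol by default."""
    if "_" in met_id:
        suffix = met_id.rsplit("_", 1)[1]
        if suffix.isalpha() and len(suffix) <= 2:
            return suffix
    return "c"


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts from a Hill-style formula token, e.g. C6H12O6."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ModelValidationError(f"unparseable formula {formula!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ModelValidationError(f"unparseable formula {formula!r}")
    return counts


@dataclass
class ValidationReport:
    """Report-only model diagnostics; empty lists mean a clean model."""

    orphan_metabolites: list[str] = field(default_factory=list)
    missing_metabolites: list[str] = field(default_factory=list)
    bound_violations: list[str] = field(default_factory=list)
    unbalanced_reactions: list[str] = field(default_factory=list)
    missing_objective: bool = False

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_metabolites
            or self.missing_metabolites
            or self.bound_violations
            or self.unbalanced_reactions
            or self.missing_objective
        )


def validate_model(model: MetabolicModel, element_check: bool = False) -> ValidationReport:
    """Structural (and optionally elemental) diagnostics for a model.

    Elemental balance is only assessed for interior reactions whose
    participants all carry formulas; boundary pseudo-reactions (exchanges,
    sinks) and the biomass objective are excluded, as is conventional.
    """
    report = ValidationReport()
    used: set[str] = set()
    for rxn in model.reactions.values():
        used.update(rxn.stoichiometry)
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                report.missing_metabolites.append(f"{rxn.id}:{mid}")
        if rxn.lower_bound > rxn.upper_bound:
            report.bound_violations.append(rxn.id)
    report.orphan_metabolites = sorted(set(model.metabolites) - used)
    if model.objective_id is None or model.objective_id not in model.reactions:
        report.missing_objective = True

    if element_check:
        for rxn in model.reactions.values():
            if rxn.boundary or rxn.id == model.objective_id:
                continue
            formulas = [
                model.metabolites[m].formula
                for m in rxn.stoichiometry
                if m in model.metabolites
            ]
            if any(f is None for f in formulas) or len(formulas) < len(rxn.stoichiometry):
                continue
            balance: dict[str, float] = {}
            for mid, coef in rxn.stoichiometry.items():
                for element, n in parse_formula(model.metabolites[mid].formula).items():
                    balance[element] = balance.get(element, 0.0) + coef * n
            if any(abs(v) > 1e-9 for v in balance.values()):
                report.unbalanced_reactions.append(rxn.id)
    report.unbalanced_reactions.sort()
    return report
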