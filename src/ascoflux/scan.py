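"""Overexpression-target identification by flux amplification + MOMA.

For every reaction carrying flux in the wild-type reference, the scan
imposes an amplified flux v_j = k * v_ref,j (sign-preserving; overexpression
speeds the direction the reaction already runs), re-solves the network by
MOMA, and scores the perturbation with

    f_PH = f_biomass * f_ascomycin
         = (v_biomass,over / v_biomass,wild) * (v_product,over / v_product,wild)

A target that raises product flux without wrecking growth scores f_PH > 1;
the ranking orders candidates by f_PH descending. The wild-type reference is
computed with the product flux's lower bound at a small baseline so the
product denominator is non-zero; during perturbation the product flux stays
free above that same baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .builder import BoundEdit
from .fba import FluxDistribution, fix_flux, reference_flux
from .model import MetabolicModel
from .moma import moma

__all__ = [
    "PerturbationScores",
    "TargetRanking",
    "compute_fph",
    "wild_type_reference",
    "scan_targets",
    "count_targets",
]

#: |v_ref| below this is treated as zero flux (reaction not scanned)
ZERO_FLUX_TOL = 1e-9


@dataclass
class PerturbationScores:
    """Scores for one amplified reaction (status 'scored' when solvable)."""

    reaction_id: str
    subsystem: str
    v_wild: float
    v_amplified: float
    f_biomass: float = float("nan")
    f_ascomycin: float = float("nan")
    f_ph: float = float("nan")
    status: str = "scored"  # "scored" | "infeasible" | "excluded"


@dataclass
class TargetRanking:
    """Scored rows sorted by f_PH descending (ties: reaction id ascending);
    infeasible rows trail the scored ones."""

    rows: list[PerturbationScores]
    k: float
    objective_id: str
    product_id: str
    exclude_subsystems: tuple[str, ...] = ()
    exclude_reactions: tuple[str, ...] = ()

    def scored(self) -> list[PerturbationScores]:
        return [r for r in self.rows if r.status == "scored"]

    def to_table(self) -> str:
        """Deterministic TSV rendering (rank, id, subsystem, fluxes, scores)."""
        lines = [
            "rank\treaction_id\tsubsystem\tv_wild\tv_amplified\tf_biomass\tf_ascomycin\tf_ph\tstatus"
        ]
        for rank, row in enumerate(self.rows, start=1):
            lines.append(
                f"{rank}\t{row.reaction_id}\t{row.subsystem}\t{row.v_wild:.10g}\t"
                f"{row.v_amplified:.10g}\t{row.f_biomass:.10g}\t{row.f_ascomycin:.10g}\t"
                f"{row.f_ph:.10g}\t{row.status}"
            )
        return "\n".join(lines) + "\n"


def compute_fph(
    v_bio_wild: float, v_bio_over: float, v_asc_wild: float, v_asc_over: float
) -> tuple[float, float, float]:
    """(f_biomass, f_ascomycin, f_PH) from the four rate values."""
    if v_bio_wild <= 0:
        raise ValueError(f"wild-type biomass flux must be > 0, got {v_bio_wild}")
    if v_asc_wild <= 0:
        raise ValueError(f"wild-type product flux must be > 0, got {v_asc_wild}")
    f_biomass = v_bio_over / v_bio_wild
    f_ascomycin = v_asc_over / v_asc_wild
    return f_biomass, f_ascomycin, f_biomass * f_ascomycin


def wild_type_reference(
    model: MetabolicModel,
    product_baseline: float | None = None,
    extra_bounds: list[BoundEdit] | None = None,
) -> FluxDistribution:
    """Parsimonious wild-type reference with the product flux floored.

    ``product_baseline`` raises the product reaction's lower bound so the
    f_PH denominator is non-zero (the same baseline the validation
    simulation fixes); it never lowers an already higher bound.
    """
    bounds = list(extra_bounds or [])
    if product_baseline is not None:
        if model.product_id is None:
            raise ValueError("model has no product reaction; cannot set baseline")
        current = model.reactions[model.product_id].lower_bound
        bounds.append(
            BoundEdit(model.product_id, "lower", max(current, product_baseline))
        )
    return reference_flux(model, bounds)


def scan_targets(
    model: MetabolicModel,
    reference: FluxDistribution,
    k: float = 2.0,
    exclude_subsystems: tuple[str, ...] | list[str] = (),
    exclude_reactions: tuple[str, ...] | list[str] = (),
    extra_bounds: list[BoundEdit] | None = None,
    product_baseline: float | None = None,
    min_mode: bool = False,
) -> TargetRanking:
    """Amplify every non-zero-flux, non-excluded reaction and rank by f_PH.

    ``product_baseline`` keeps the product flux's lower bound at the same
    floor the wild-type reference was computed with — the perturbed product
    flux is free above that bound, not free to collapse to zero.
    ``min_mode`` imposes the amplified flux as a one-sided (at-least) bound
    instead of an equality; the default equality is the strict reading of a
    forced overexpression flux. Infeasible amplifications are kept in the
    ranking with status ``infeasible`` and never abort the scan.
    """
    if k <= 1.0:
        # k = 1 is the identity perturbation and is allowed for calibration
        if k < 1.0:
            raise ValueError(f"amplification factor must be >= 1, got {k}")
    if not reference.optimal:
        raise ValueError("reference flux distribution is not optimal")
    if model.objective_id not in reference.fluxes:
        raise ValueError("reference lacks the objective reaction")
    if model.product_id is None or model.product_id not in reference.fluxes:
        raise ValueError("reference lacks the product reaction")
    v_bio_wild = reference.fluxes[model.objective_id]
    v_asc_wild = reference.fluxes[model.product_id]
    excl_sub = set(exclude_subsystems)
    excl_rxn = set(exclude_reactions)
    base_bounds = list(extra_bounds or [])
    if product_baseline is not None:
        current = model.reactions[model.product_id].lower_bound
        base_bounds.append(
            BoundEdit(model.product_id, "lower", max(current, product_baseline))
        )

    rows: list[PerturbationScores] = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        v_ref = reference.fluxes[rid]
        if abs(v_ref) <= ZERO_FLUX_TOL:
            continue
        if rxn.subsystem in excl_sub or rid in excl_rxn:
            continue
        v_amp = k * v_ref
        if min_mode:
            which = "lower" if v_ref > 0 else "upper"
            perturbation = [BoundEdit(rid, which, v_amp)]
        else:
            perturbation = fix_flux(rid, v_amp)
        solution = moma(model, reference, base_bounds + perturbation)
        row = PerturbationScores(
            reaction_id=rid, subsystem=rxn.subsystem, v_wild=v_ref, v_amplified=v_amp
        )
        if solution.optimal:
            row.f_biomass, row.f_ascomycin, row.f_ph = compute_fph(
                v_bio_wild,
                solution.fluxes[model.objective_id],
                v_asc_wild,
                solution.fluxes[model.product_id],
            )
        else:
            row.status = "infeasible"
        rows.append(row)

    scored = sorted(
        (r for r in rows if r.status == "scored"),
        key=lambda r: (-r.f_ph, r.reaction_id),
    )
    infeasible = sorted(
        (r for r in rows if r.status != "scored"), key=lambda r: r.reaction_id
    )
    return TargetRanking(
        rows=scored + infeasible,
        k=k,
        objective_id=model.objective_id,
        product_id=model.product_id,
        exclude_subsystems=tuple(exclude_subsystems),
        exclude_reactions=tuple(exclude_reactions),
    )


def count_targets(
    ranking: TargetRanking,
    threshold: float = 1.0,
    secondary_subsystems: set[str] | frozenset[str] = frozenset(),
) -> dict[str, int]:
    """Count scored rows with f_PH above threshold, split primary/secondary."""
    total = primary = secondary = 0
    for row in ranking.scored():
        if row.f_ph > threshold:
            total += 1
            if row.subsystem in secondary_subsystems:
                secondary += 1
            else:
                primary += 1
    return {"total": total, "primary": primary, "secondary": secondary}
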