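"""Derive a product-specific model from a base model by scripted edits.

The curation recipe this module implements mirrors how a polyketide
producer's model is derived from a well-curated relative: delete the donor's
own secondary-metabolite subsystems, add the product's precursor-supply and
assembly reactions, and pin a handful of bounds to experimentally supported
values (cofactor specificity of the oxidative pentose-phosphate entry,
glucose phosphorylation route, minimal PP-pathway and anaplerotic fluxes).

Edits are applied in a fixed order — removals, then additions, then bound
edits — so a bound edit may target a freshly added reaction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import DEFAULT_BOUND, MetabolicModel, ModelValidationError, Reaction

__all__ = [
    "BoundEdit",
    "EditScript",
    "remove_subsystems",
    "apply_edit_script",
    "complete_emc_pathway",
    "EMC_PATHWAY_STEPS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundEdit:
    """Set one bound of one reaction to an absolute value."""

    reaction_id: str
    which: str  # "lower" | "upper"
    value: float

    def __post_init__(self) -> None:
        if self.which not in ("lower", "upper"):
            raise ValueError(f"which must be 'lower' or 'upper', got {self.which!r}")


@dataclass
class EditScript:
    """Declarative model-curation script (JSON/YAML serializable)."""

    remove_subsystems: list[str] = field(default_factory=list)
    remove_reactions: list[str] = field(default_factory=list)
    add_reactions: list[Reaction] = field(default_factory=list)
    bound_edits: list[BoundEdit] = field(default_factory=list)
    drop_orphans: bool = True

    def __post_init__(self) -> None:
        added = {r.id for r in self.add_reactions}
        clash = added & set(self.remove_reactions)
        if clash:
            raise ValueError(f"reactions both removed and added: {sorted(clash)}")

    @classmethod
    def from_dict(cls, payload: dict) -> "EditScript":
        adds = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={m: float(c) for m, c in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                subsystem=r.get("subsystem", ""),
                genes=list(r.get("genes", [])),
            )
            for r in payload.get("add_reactions", [])
        ]
        edits = [
            BoundEdit(e["reaction_id"], e["which"], float(e["value"]))
            for e in payload.get("bound_edits", [])
        ]
        return cls(
            remove_subsystems=list(payload.get("remove_subsystems", [])),
            remove_reactions=list(payload.get("remove_reactions", [])),
            add_reactions=adds,
            bound_edits=edits,
            drop_orphans=bool(payload.get("drop_orphans", True)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "EditScript":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.from_dict(payload)


def remove_subsystems(
    model: MetabolicModel, names: list[str], drop_orphans: bool = True
) -> MetabolicModel:
    """Drop every reaction carrying one of the named subsystem tokens.

    The objective reaction is never removed; asking for its subsystem is an
    error. Removals naming subsystems absent from the model are logged and
    ignored.
    """
    if not names:
        raise ValueError("names must be non-empty")
    present = {r.subsystem for r in model.reactions.values()}
    for name in names:
        if name not in present:
            logger.warning("subsystem %r not present in model %s; skipping", name, model.id)
    objective = model.objective
    if objective.subsystem in names:
        raise ModelValidationError(
            f"refusing to remove subsystem {objective.subsystem!r} containing the "
            f"objective reaction {objective.id!r}"
        )
    out = model.copy()
    doomed = [r.id for r in out.reactions.values() if r.subsystem in set(names)]
    for rid in doomed:
        out.remove_reaction(rid)
    if drop_orphans:
        _drop_orphan_metabolites(out)
    return out


def _drop_orphan_metabolites(model: MetabolicModel) -> None:
    used: set[str] = set()
    for rxn in model.reactions.values():
        used.update(rxn.stoichiometry)
    for mid in sorted(set(model.metabolites) - used):
        del model.metabolites[mid]


def apply_edit_script(model: MetabolicModel, script: EditScript) -> MetabolicModel:
    """Apply removals, then additions, then bound edits; returns a new model."""
    out = model.copy()
    if script.remove_subsystems:
        out = remove_subsystems(out, script.remove_subsystems, drop_orphans=False)
    for rid in script.remove_reactions:
        if rid == out.objective_id:
            raise ModelValidationError("refusing to remove the objective reaction")
        if rid in out.reactions:
            out.remove_reaction(rid)
        else:
            logger.warning("remove_reactions: %r not in model; skipping", rid)
    for rxn in script.add_reactions:
        out.add_reaction(rxn, allow_new_metabolites=True)
    for edit in script.bound_edits:
        if edit.reaction_id not in out.reactions:
            raise ModelValidationError(
                f"bound edit targets unknown reaction {edit.reaction_id!r}"
            )
        rxn = out.reactions[edit.reaction_id]
        if edit.which == "lower":
            rxn.lower_bound = edit.value
        else:
            rxn.upper_bound = edit.value
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"bound edit leaves {rxn.id!r} with lower {rxn.lower_bound} > "
                f"upper {rxn.upper_bound}"
            )
    if script.drop_orphans:
        _drop_orphan_metabolites(out)
    return out


#: Canonical ethylmalonyl-CoA pathway steps (acetyl-CoA condensation through
#: reductive carboxylation of crotonyl-CoA), with cofactor-free bookkeeping
#: stoichiometries matching the toy fixtures in :mod:`ascoflux.synth`.
EMC_PATHWAY_STEPS: dict[str, dict] = {
    "ACACT1r": {
        "name": "acetyl-CoA C-acetyltransferase",
        "metabolites": {"accoa_c": -2.0, "aacoa_c": 1.0},
        "lower_bound": -DEFAULT_BOUND,
        "upper_bound": DEFAULT_BOUND,
        "genes": ["acat"],
    },
    "HACD1": {
        "name": "3-hydroxybutyryl-CoA dehydrogenase",
        "metabolites": {"aacoa_c": -1.0, "hbcoa_c": 1.0},
        "lower_bound": 0.0,
        "upper_bound": DEFAULT_BOUND,
        "genes": ["hcd"],
    },
    "ECOAH1": {
        "name": "3-hydroxybutyryl-CoA dehydratase",
        "metabolites": {"hbcoa_c": -1.0, "b2coa_c": 1.0, "h2o_c": 1.0},
        "lower_bound": 0.0,
        "upper_bound": DEFAULT_BOUND,
        "genes": ["ech"],
    },
    "CCCR": {
        "name": "crotonyl-CoA carboxylase/reductase",
        "metabolites": {"b2coa_c": -1.0, "co2_c": -1.0, "emcoa_c": 1.0},
        "lower_bound": 0.0,
        "upper_bound": DEFAULT_BOUND,
        "genes": ["ccr"],
    },
}


def complete_emc_pathway(model: MetabolicModel) -> MetabolicModel:
    """Add any missing ethylmalonyl-CoA pathway step; idempotent.

    Reactions already present (by id) are left untouched, so applying this
    twice equals applying it once.
    """
    out = model.copy()
    for rid, payload in EMC_PATHWAY_STEPS.items():
        if rid in out.reactions:
            continue
        out.add_reaction(
            Reaction(
                id=rid,
                name=payload["name"],
                stoichiometry=dict(payload["metabolites"]),
                lower_bound=payload["lower_bound"],
                upper_bound=payload["upper_bound"],
                subsystem="emc_pathway",
                genes=list(payload["genes"]),
            ),
            allow_new_metabolites=True,
        )
    return out
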