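"""Read and write metabolic models in TSV, JSON and SBML (L3 + FBC) dialects.

TSV reaction table
    Tab-separated, UTF-8, header row required, columns::

        rxn_id  name  equation  lower_bound  upper_bound  subsystem  genes

    Equation grammar: ``2 glc_c + atp_c -> g6p_c`` (irreversible) or
    ``A_c <=> B_c`` (reversible); coefficients optional (default 1);
    the metabolite compartment is the trailing ``_c``/``_e`` suffix.
    Empty bounds default to (-1000, 1000) for ``<=>`` and (0, 1000) for
    ``->``. Genes are comma-separated. Lines starting with ``#`` are
    comments. Metabolite formulas are not representable in this dialect.

JSON schema (documented here; see also README)
    Object with keys ``id``, ``objective_id``, ``product_id`` (nullable),
    ``metabolites`` (list of {id, name, compartment, formula}) and
    ``reactions`` (list of {id, name, metabolites: {met_id: coefficient},
    lower_bound, upper_bound, subsystem, genes}).

SBML
    Level 3 Version 1 with the ``fbc`` v2 package: species formulas via
    fbc:chemicalFormula, bounds via fbc flux-bound parameters, the
    objective via an fbc objective; the subsystem, gene list and product
    reaction are stored in notes (annotation round-trip beyond this is a
    non-goal).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    _compartment_of,
)

__all__ = ["load_model", "save_model", "parse_equation", "format_equation", "FormatError"]

TSV_COLUMNS = ["rxn_id", "name", "equation", "lower_bound", "upper_bound", "subsystem", "genes"]

_COEF_RE = re.compile(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)$")


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the named dialect."""


# ---------------------------------------------------------------------------
# equation grammar


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A_c + B_c -> C_c`` into (stoichiometry, reversible)."""
    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "->" in text:
        arrow, reversible = "->", False
    else:
        raise FormatError(f"equation {text!r} has no '->' or '<=>' arrow")
    left, _, right = text.partition(arrow)
    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            tokens = term.split()
            if not tokens:
                continue
            if len(tokens) == 2 and _COEF_RE.match(tokens[0]):
                coef, met = float(tokens[0]), tokens[1]
            elif len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            else:
                raise FormatError(f"unparseable equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _accumulate(left, -1.0)
    _accumulate(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise FormatError(f"equation {text!r} has empty net stoichiometry")
    return stoich, reversible


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def _side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coef in items:
            parts.append(met if coef == 1.0 else f"{coef:g} {met}")
        return " + ".join(parts)

    subs = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    prods = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{_side(subs)} {arrow} {_side(prods)}".strip()


# ---------------------------------------------------------------------------
# dispatch


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model; the format is inferred from the suffix when omitted."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _load_tsv(path)
    if fmt == "json":
        return _load_json(path)
    if fmt == "sbml":
        return _load_sbml(path)
    raise FormatError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model; load_model(save_model(m)) preserves ids, stoichiometry,
    bounds and subsystems in every dialect."""
    from .model import validate_model

    report = validate_model(model)
    if report.missing_metabolites or report.bound_violations or report.missing_objective:
        raise ModelValidationError(f"refusing to write invalid model: {report}")
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _save_tsv(model, path)
    elif fmt == "json":
        _save_json(model, path)
    elif fmt == "sbml":
        _save_sbml(model, path)
    else:
        raise FormatError(f"unknown model format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix == ".json":
        return "json"
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    raise FormatError(f"cannot infer model format from {path.name!r}")


# ---------------------------------------------------------------------------
# TSV


def _load_tsv(path: Path) -> MetabolicModel:
    model = MetabolicModel(id=path.stem)
    lines = path.read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in TSV_COLUMNS if c not in header]
            if missing:
                raise FormatError(f"{path}:{lineno}: missing TSV columns {missing}")
            continue
        row = dict(zip(header, fields))
        try:
            stoich, reversible = parse_equation(row["equation"])
            lb_text = row.get("lower_bound", "").strip()
            ub_text = row.get("upper_bound", "").strip()
            lb = float(lb_text) if lb_text else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_text) if ub_text else DEFAULT_BOUND
            genes_text = row.get("genes", "").strip()
            rxn = Reaction(
                id=row["rxn_id"].strip(),
                name=row.get("name", "").strip(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=row.get("subsystem", "").strip(),
                genes=[g.strip() for g in genes_text.split(",") if g.strip()],
            )
        except (ModelValidationError, FormatError, ValueError, KeyError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        model.add_reaction(rxn, allow_new_metabolites=True)
    if header is None:
        raise FormatError(f"{path}: empty TSV reaction table")
    # biomass convention: a reaction id starting BIO* or containing "biomass"
    # is taken as the objective (the TSV dialect has no objective column)
    for rid in model.reactions:
        if rid.upper().startswith("BIO") or "biomass" in rid.lower():
            model.objective_id = rid
            break
    return model


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    lines = ["\t".join(TSV_COLUMNS)]
    for rxn in model.reactions.values():
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn.stoichiometry, rxn.reversible),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    rxn.subsystem,
                    ",".join(rxn.genes),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON


def _load_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        model = MetabolicModel(id=payload.get("id", path.stem))
        for met in payload["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    id=met["id"],
                    name=met.get("name", ""),
                    compartment=met.get("compartment", "c"),
                    formula=met.get("formula"),
                )
            )
        for rxn in payload["reactions"]:
            model.add_reaction(
                Reaction(
                    id=rxn["id"],
                    name=rxn.get("name", ""),
                    stoichiometry={m: float(c) for m, c in rxn["metabolites"].items()},
                    lower_bound=float(rxn.get("lower_bound", -DEFAULT_BOUND)),
                    upper_bound=float(rxn.get("upper_bound", DEFAULT_BOUND)),
                    subsystem=rxn.get("subsystem", ""),
                    genes=list(rxn.get("genes", [])),
                )
            )
        model.objective_id = payload.get("objective_id")
        model.product_id = payload.get("product_id")
    except (KeyError, TypeError, ModelValidationError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return model


def _save_json(model: MetabolicModel, path: Path) -> None:
    payload = {
        "id": model.id,
        "objective_id": model.objective_id,
        "product_id": model.product_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "genes": r.genes,
            }
            for r in model.reactions.values()
        ],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# SBML (libsbml, FBC v2)


def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no <model> element")
    model = MetabolicModel(id=sbml_model.getId() or path.stem)

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        fbc_rx = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if fbc_rx is not None:
            lb_param = sbml_model.getParameter(fbc_rx.getLowerFluxBound())
            ub_param = sbml_model.getParameter(fbc_rx.getUpperFluxBound())
            if lb_param is not None:
                lb = lb_param.getValue()
            if ub_param is not None:
                ub = ub_param.getValue()
        notes = _parse_notes(rx.getNotesString() if rx.isSetNotes() else "")
        genes = [g for g in notes.get("GENES", "").split(",") if g]
        model.add_reaction(
            Reaction(
                id=_strip_prefix(rx.getId(), "R_"),
                name=rx.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=notes.get("SUBSYSTEM", ""),
                genes=genes,
            )
        )

    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = _strip_prefix(obj.getFluxObjective(0).getReaction(), "R_")
    model_notes = _parse_notes(sbml_model.getNotesString() if sbml_model.isSetNotes() else "")
    model.product_id = model_notes.get("PRODUCT_REACTION") or None
    return model


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id(model.id))
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(True)
    if model.product_id:
        _set_notes(sbml_model, {"PRODUCT_REACTION": model.product_id})

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(_sbml_id(comp_id))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sbml_id(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sbml_id(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula is not None:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId("R_" + _sbml_id(rxn.id))
        rx.setName(rxn.name)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies("M_" + _sbml_id(mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        fbc_rx = rx.getPlugin("fbc")
        fbc_rx.setLowerFluxBound(_bound_param(rxn.lower_bound))
        fbc_rx.setUpperFluxBound(_bound_param(rxn.upper_bound))
        notes = {}
        if rxn.subsystem:
            notes["SUBSYSTEM"] = rxn.subsystem
        if rxn.genes:
            notes["GENES"] = ",".join(rxn.genes)
        if notes:
            _set_notes(rx, notes)

    if model.objective_id is not None:
        objective = fbc_model.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction("R_" + _sbml_id(model.objective_id))
        flux_obj.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def _sbml_id(token: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", token)


def _strip_prefix(token: str, prefix: str) -> str:
    return token[len(prefix):] if token.startswith(prefix) else token


def _set_notes(element, mapping: dict[str, str]) -> None:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in mapping.items())
    element.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _parse_notes(notes_xml: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for match in re.finditer(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", notes_xml, re.S):
        out[match.group(1)] = match.group(2)
    return out
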