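"""Synthetic desk-scale inputs for the whole pipeline.

Three generator families:

* parameterized branched toy networks (:func:`make_toy_model`) — a glucose
  input feeding competing branches of known integer yield into a biomass
  sink, optionally with a polyketide-product branch fed by an
  ethylmalonyl-CoA-like precursor chain;
* a fixed, curated ascomycin-like fixture (:func:`make_core_ascomycin_toy`)
  whose reaction ids mirror the canonical pathway steps (ACACT1r, HACD1,
  ECOAH1, CCCR, MME, MMM) so curation and scan behaviour can be asserted by
  name;
* alignment hit tables with planted conservation structure
  (:func:`make_hit_table`) whose planted fractions the conservation
  pipeline recovers exactly.

Every generator is a pure function of its spec (and seed): repeated calls
produce byte-identical artifacts. Metabolite formulas are small CxHyOz
pseudo-formulas chosen so each interior reaction is elementally balanced,
which keeps the element check exact; branch yields are therefore restricted
to integers 1..6 (a yield-y branch splits C6H12O6 into y + (6-y) CH2O
units).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelSpec",
    "HitTableSpec",
    "make_toy_model",
    "make_core_ascomycin_toy",
    "make_hit_table",
    "random_small_model",
]

#: product-flux baseline used by the curated fixture's validation scenario,
#: matching the magnitude a producer strain secretes relative to growth
PRODUCT_BASELINE = 5e-4


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of a branched toy network; fully determines the model."""

    n_branches: int = 2
    branch_yields: tuple[int, ...] = (1, 2)
    include_emc_branch: bool = True
    product_stoichiometry: tuple[tuple[str, float], ...] = (("emcoa_c", 1.0),)
    uptake_limit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if len(self.branch_yields) != self.n_branches:
            raise ValueError("branch_yields length must equal n_branches")
        for y in self.branch_yields:
            if int(y) != y or not (1 <= int(y) <= 6):
                raise ValueError(
                    f"branch yields must be integers in 1..6 (element balance), got {y}"
                )


@dataclass(frozen=True)
class HitTableSpec:
    """Planted-conservation hit-table parameters."""

    n_queries: int = 200
    strains: tuple[str, ...] = ("S14-shy", "S16-shyl")
    planted_fraction: tuple[tuple[str, float], ...] = (
        ("S14-shy", 0.75),
        ("S16-shyl", 0.75),
    )
    n_subsystems: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = dict(self.planted_fraction)
        for strain in self.strains:
            f = fractions.get(strain)
            if f is None or not (0.0 <= f <= 1.0):
                raise ValueError(f"planted fraction for {strain!r} must be in [0, 1]")
            if abs(f * self.n_queries - round(f * self.n_queries)) > 1e-9:
                raise ValueError(
                    f"fraction {f} x {self.n_queries} queries is not an integer; "
                    "exact recovery impossible"
                )


def make_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    """Branched toy network; FBA routes all carbon through the best branch."""
    model = MetabolicModel(id=f"toy_b{spec.n_branches}_s{spec.seed}")
    _add_met = model.add_metabolite
    _add_met(Metabolite("glc_e", "glucose (external)", "e", "C6H12O6"))
    _add_met(Metabolite("glc_c", "glucose", "c", "C6H12O6"))
    _add_met(Metabolite("pre_c", "biomass precursor unit", "c", "CH2O"))
    _add_met(Metabolite("w_c", "byproduct unit", "c", "CH2O"))
    model.add_reaction(
        Reaction(
            "EX_glc",
            {"glc_e": 1.0},
            name="glucose supply",
            lower_bound=0.0,
            upper_bound=spec.uptake_limit,
            subsystem="exchange",
        )
    )
    model.add_reaction(
        Reaction(
            "GLCt",
            {"glc_e": -1.0, "glc_c": 1.0},
            name="glucose transport",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="transport",
        )
    )
    for i, y in enumerate(spec.branch_yields, start=1):
        y = int(y)
        stoich: dict[str, float] = {"glc_c": -1.0, "pre_c": float(y)}
        if y < 6:
            stoich["w_c"] = float(6 - y)
        model.add_reaction(
            Reaction(
                f"BR{i}",
                stoich,
                name=f"branch {i} (yield {y})",
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                subsystem="central_carbon",
            )
        )
    model.add_reaction(
        Reaction(
            "EX_w",
            {"w_c": -1.0},
            name="byproduct drain",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="exchange",
        )
    )
    model.add_reaction(
        Reaction(
            "BIO",
            {"pre_c": -1.0},
            name="biomass",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="biomass",
        )
    )
    model.objective_id = "BIO"
    if spec.include_emc_branch:
        _add_emc_product_branch(model, dict(spec.product_stoichiometry))
    return model


def _add_emc_product_branch(model: MetabolicModel, product_stoich: dict[str, float]) -> None:
    """Ethylmalonyl-CoA-like precursor chain + product synthesis/export."""
    for met in (
        Metabolite("accoa_c", "acetyl unit", "c", "C2H4O2"),
        Metabolite("aacoa_c", "acetoacetyl unit", "c", "C4H8O4"),
        Metabolite("hbcoa_c", "3-hydroxybutyryl unit", "c", "C4H8O4"),
        Metabolite("b2coa_c", "crotonyl unit", "c", "C4H6O3"),
        Metabolite("emcoa_c", "ethylmalonyl unit", "c", "C5H6O5"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("h2o_c", "water", "c", "H2O"),
        Metabolite("prod_c", "polyketide product", "c", None),
    ):
        if met.id not in model.metabolites:
            model.add_metabolite(met)
    model.add_reaction(
        Reaction(
            "PREX",
            {"pre_c": -2.0, "accoa_c": 1.0},
            name="precursor to acetyl unit",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="central_carbon",
        )
    )
    for rid, stoich, lb in (
        ("ACACT1r", {"accoa_c": -2.0, "aacoa_c": 1.0}, -DEFAULT_BOUND),
        ("HACD1", {"aacoa_c": -1.0, "hbcoa_c": 1.0}, 0.0),
        ("ECOAH1", {"hbcoa_c": -1.0, "b2coa_c": 1.0, "h2o_c": 1.0}, 0.0),
        ("CCCR", {"b2coa_c": -1.0, "co2_c": -1.0, "emcoa_c": 1.0}, 0.0),
    ):
        model.add_reaction(
            Reaction(
                rid,
                stoich,
                lower_bound=lb,
                upper_bound=DEFAULT_BOUND,
                subsystem="emc_pathway",
            )
        )
    model.add_reaction(
        Reaction(
            "PRODS",
            {**{m: -c for m, c in product_stoich.items()}, "prod_c": 1.0},
            name="product synthesis",
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            subsystem="product_synthesis",
        )
    )
    for rid, stoich in (("EX_prod", {"prod_c": -1.0}), ("EX_co2", {"co2_c": 1.0}), ("EX_h2o", {"h2o_c": -1.0})):
        model.add_reaction(
            Reaction(
                rid,
                stoich,
                lower_bound=-DEFAULT_BOUND if rid == "EX_co2" else 0.0,
                upper_bound=DEFAULT_BOUND,
                subsystem="exchange",
            )
        )
    model.product_id = "EX_prod"
    model.reactions["EX_prod"].lower_bound = 0.0


def make_core_ascomycin_toy() -> MetabolicModel:
    """Fixed curated ascomycin-like fixture (byte-stable across releases).

    Glucose feeds a lumped glycolysis yielding acetyl units; the
    ethylmalonyl-CoA-like chain (ACACT1r -> HACD1 -> ECOAH1 -> CCCR) and a
    methylmalonyl route (SUCOAS_L -> MMM -> MME) plus a malonyl route (ACC)
    supply the product assembly reaction ASCS; biomass drains acetyl and
    malonyl units and a forced maintenance drain competes for acetyl units.
    The product export EX_asco is the designated product flux.
    """
    mets = [
        Metabolite("glc_e", "glucose (external)", "e", "C6H12O6"),
        Metabolite("glc_c", "glucose", "c", "C6H12O6"),
        Metabolite("accoa_c", "acetyl unit", "c", "C2H4O2"),
        Metabolite("aacoa_c", "acetoacetyl unit", "c", "C4H8O4"),
        Metabolite("hbcoa_c", "3-hydroxybutyryl unit", "c", "C4H8O4"),
        Metabolite("b2coa_c", "crotonyl unit", "c", "C4H6O3"),
        Metabolite("emcoa_c", "ethylmalonyl unit", "c", "C5H6O5"),
        Metabolite("succoa_c", "succinyl unit", "c", "C4H8O4"),
        Metabolite("mmcoa_c", "(R)-methylmalonyl unit", "c", "C4H8O4"),
        Metabolite("mmacoa_c", "(S)-methylmalonyl unit", "c", "C4H8O4"),
        Metabolite("malcoa_c", "malonyl unit", "c", "C3H4O4"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("h2o_c", "water", "c", "H2O"),
        Metabolite("asco_c", "ascomycin-like product", "c", "C11H18O11"),
    ]
    rxns = [
        Reaction("EX_glc", {"glc_e": 1.0}, name="glucose supply", lower_bound=0.0,
                 upper_bound=1.0, subsystem="exchange"),
        Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, name="glucose transport",
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, subsystem="transport"),
        Reaction("GLYC", {"glc_c": -1.0, "accoa_c": 3.0}, name="lumped glycolysis",
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, subsystem="glycolysis"),
        Reaction("ACACT1r", {"accoa_c": -2.0, "aacoa_c": 1.0},
                 name="acetyl-CoA C-acetyltransferase", lower_bound=-DEFAULT_BOUND,
                 upper_bound=DEFAULT_BOUND, subsystem="emc_pathway", genes=["acat"]),
        Reaction("HACD1", {"aacoa_c": -1.0, "hbcoa_c": 1.0},
                 name="3-hydroxybutyryl-CoA dehydrogenase", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="emc_pathway", genes=["hcd"]),
        Reaction("ECOAH1", {"hbcoa_c": -1.0, "b2coa_c": 1.0, "h2o_c": 1.0},
                 name="3-hydroxybutyryl-CoA dehydratase", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="emc_pathway", genes=["ech"]),
        Reaction("CCCR", {"b2coa_c": -1.0, "co2_c": -1.0, "emcoa_c": 1.0},
                 name="crotonyl-CoA carboxylase/reductase", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="emc_pathway", genes=["ccr"]),
        Reaction("ACC", {"accoa_c": -1.0, "co2_c": -1.0, "malcoa_c": 1.0},
                 name="acetyl-CoA carboxylase", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="precursor_supply"),
        Reaction("SUCOAS_L", {"accoa_c": -2.0, "succoa_c": 1.0},
                 name="lumped TCA to succinyl unit", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="precursor_supply"),
        Reaction("MMM", {"succoa_c": -1.0, "mmcoa_c": 1.0},
                 name="methylmalonyl-CoA mutase", lower_bound=-DEFAULT_BOUND,
                 upper_bound=DEFAULT_BOUND, subsystem="precursor_supply", genes=["mcm"]),
        Reaction("MME", {"mmcoa_c": -1.0, "mmacoa_c": 1.0},
                 name="methylmalonyl-CoA epimerase", lower_bound=-DEFAULT_BOUND,
                 upper_bound=DEFAULT_BOUND, subsystem="precursor_supply", genes=["mce"]),
        Reaction("ASCS", {"emcoa_c": -1.0, "mmacoa_c": -1.0, "malcoa_c": -1.0,
                          "asco_c": 1.0, "co2_c": 1.0},
                 name="product assembly", lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                 subsystem="product_synthesis", genes=["fkbB"]),
        Reaction("EX_asco", {"asco_c": -1.0}, name="product export", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="exchange"),
        Reaction("EX_co2", {"co2_c": 1.0}, name="CO2 exchange",
                 lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND,
                 subsystem="exchange"),
        Reaction("EX_h2o", {"h2o_c": -1.0}, name="water drain", lower_bound=0.0,
                 upper_bound=DEFAULT_BOUND, subsystem="exchange"),
        Reaction("DRAIN", {"accoa_c": -1.0}, name="maintenance drain",
                 lower_bound=0.05, upper_bound=DEFAULT_BOUND, subsystem="maintenance"),
        Reaction("BIO", {"accoa_c": -2.0, "malcoa_c": -1.0}, name="biomass",
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, subsystem="biomass"),
    ]
    return MetabolicModel(
        id="core_ascomycin_toy",
        metabolites=mets,
        reactions=rxns,
        objective_id="BIO",
        product_id="EX_asco",
    )


def random_small_model(seed: int, max_reactions: int = 6) -> MetabolicModel:
    """Random tiny model with finite bounds, always feasible (v = 0 works).

    Used as raw material for cross-checking the LP/QP solvers against the
    brute-force enumerators; carries no formulas (element check vacuous).
    """
    rng = random.Random(seed)
    n_rxn = rng.randint(3, max_reactions)
    n_met = rng.randint(1, max(1, n_rxn - 1))
    met_ids = [f"m{i}_c" for i in range(n_met)]
    model = MetabolicModel(id=f"rand_{seed}")
    for mid in met_ids:
        model.add_metabolite(Metabolite(mid, compartment="c"))
    for j in range(n_rxn):
        stoich: dict[str, float] = {}
        for mid in met_ids:
            if rng.random() < 0.7:
                coef = rng.choice([-2.0, -1.0, 1.0, 2.0])
                stoich[mid] = coef
        if not stoich:
            stoich[rng.choice(met_ids)] = rng.choice([-1.0, 1.0])
        reversible = rng.random() < 0.5
        ub = rng.choice([1.0, 2.0, 5.0])
        lb = -rng.choice([1.0, 2.0, 5.0]) if reversible else 0.0
        model.add_reaction(
            Reaction(f"r{j}", stoich, lower_bound=lb, upper_bound=ub, subsystem="random")
        )
    model.objective_id = f"r{rng.randrange(n_rxn)}"
    return model


# ---------------------------------------------------------------------------
# planted hit tables


def make_hit_table(spec: HitTableSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write hit tables, a query-length TSV and a subsystem map; return paths.

    Per strain the first ``round(fraction * n_queries)`` queries (by index)
    receive one planted passing top hit (identity 80, full-length alignment,
    e = 1e-50); every third query additionally receives a decoy hit failing
    all three thresholds at once (identity 30, 30% coverage, e = 1e-3), so
    boundary semantics cannot perturb the planted fractions. The pipeline
    recovers each planted fraction exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    queries = [f"Q{i:04d}" for i in range(1, spec.n_queries + 1)]
    lengths = {q: 100 + (i % 50) for i, q in enumerate(queries)}
    subsystems = {
        q: f"subsystem_{i % spec.n_subsystems}" for i, q in enumerate(queries)
    }
    fractions = dict(spec.planted_fraction)

    paths: dict[str, Path] = {}
    qlen_path = out_dir / "query_lengths.tsv"
    qlen_path.write_text(
        "query_id\tlength\n" + "".join(f"{q}\t{lengths[q]}\n" for q in queries),
        encoding="utf-8",
    )
    paths["query_lengths"] = qlen_path
    submap_path = out_dir / "subsystem_map.tsv"
    submap_path.write_text(
        "query_id\tsubsystem\n" + "".join(f"{q}\t{subsystems[q]}\n" for q in queries),
        encoding="utf-8",
    )
    paths["subsystem_map"] = submap_path

    for strain in spec.strains:
        n_conserved = round(fractions[strain] * spec.n_queries)
        lines = []
        for i, q in enumerate(queries):
            qlen = lengths[q]
            if i < n_conserved:
                lines.append(
                    _hit_row(q, f"{strain}|prot{i:04d}", 80.0, qlen, 1e-50, 250.0)
                )
            if i % 3 == 0:
                lines.append(
                    _hit_row(
                        q,
                        f"{strain}|decoy{i:04d}",
                        30.0,
                        max(1, int(0.3 * qlen)),
                        1e-3,
                        35.0,
                    )
                )
        path = out_dir / f"hits_{strain}.tsv"
        path.write_text("".join(lines), encoding="utf-8")
        paths[strain] = path
    return paths


def _hit_row(
    query: str, subject: str, pident: float, length: int, evalue: float, bitscore: float
) -> str:
    qend = length
    return (
        f"{query}\t{subject}\t{pident:.1f}\t{length}\t0\t0\t1\t{qend}\t1\t{qend}\t"
        f"{evalue:.2e}\t{bitscore:.1f}\n"
    )
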