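# Methods

## The model universe

A `MetabolicModel` holds metabolites, reactions (signed stoichiometry, flux
bounds in mmol·gDCW⁻¹·h⁻¹, subsystem label, optional gene tokens), one
biomass objective reaction whose flux is the specific growth rate (h⁻¹), and
optionally one product reaction. The literature around such models sometimes
labels rates "mM/g DCW/h"; a molar concentration is not a rate, so this
package treats every bound and flux as mmol·gDCW⁻¹·h⁻¹, the standard
constraint-based convention. Default bound magnitude is 1000; absent bounds
default to (−1000, 1000) for reversible and (0, 1000) for irreversible
reactions.

Elemental validation parses Hill-style formulas and sums coefficient-weighted
atom counts per reaction; boundary pseudo-reactions (single metabolite) and
the biomass reaction are excluded, and reactions with any formula-less
participant are skipped rather than guessed at.

## Curation

`apply_edit_script` performs removals, then additions, then bound edits, in
that fixed order so a bound edit may target a freshly added reaction. The
objective reaction can never be removed and its stoichiometry is never
edited. Removals of "specific" reactions are explicit id lists, never pattern
matches, to keep edits auditable. The documented bound pins for the
ascomycin-producer derivation are absolute printed values (GND2 ub 0, GND ub
1000, G1DH ub 0, PGL lb 0.2, PPC lb 0.1); the PGL floor is applied as the
absolute 0.2 rather than a dynamic 20 %-of-uptake constraint because the
printed number is the reproducible contract — the relative reading can be
emulated by recomputing the edit value from the uptake in the caller's
script. `complete_emc_pathway` adds whichever of ACACT1r/HACD1/ECOAH1/CCCR
are missing, with cofactor-free bookkeeping stoichiometries matching the toy
fixtures; it never touches steps already present, hence is idempotent.

## FBA and the reference distribution

FBA is the LP max c·v over {S·v = 0, lb ≤ v ≤ ub}, solved with HiGHS through
scipy. FBA optima are routinely degenerate, and MOMA needs one well-defined
reference vector, so `reference_flux` re-solves with the objective pinned at
its optimum and total absolute flux minimized (split variables v = p − n,
minimize Σ(p+n)): the parsimonious secondary objective. LP columns are
assembled in lexicographic reaction-id order, making the entire solve a
deterministic function of model content — two runs, or two permutations of
the same model, give identical fluxes. No randomness exists anywhere in the
solve path; sampling in tests takes explicit seeds.

Tolerances: |S·v| ≤ 1e−6 and bound violation ≤ 1e−9 are asserted for every
optimal distribution; objective comparisons in tests use 1e−6.

## MOMA

The perturbed flux state is the Euclidean projection of the reference onto
the perturbed polytope: min Σ wᵢ(vᵢ − v_ref,i)², w = 1 by default (the
canonical choice; a weight hook exists). The QP is solved by OSQP
(eps 1e−8) and then polished exactly: bounds the iterate touches (within
1e−6) are fixed, the equality-constrained projection is solved through its
dense KKT system by least squares, and the polished point is accepted only
if it is primal feasible and its bound multipliers have the correct sign.
When the first-order iterate is too far from the optimum for its active-set
guess to be right (ADMM converges slowly when bounds span six orders of
magnitude, as with 1000-magnitude bounds and 1e−4-scale fluxes), the smooth
concave dual of the projection — v*(y) = clip(r − Sᵀy/w, lb, ub), ∇g = S·v* —
is maximized with L-BFGS-B from OSQP's dual iterate, and the clip pattern at
the dual optimum supplies the active set for a second polish attempt.
Infeasible perturbations are reported as a status, not raised, so a scan can
record and skip them.

## Target scan and f_PH

The wild-type reference is computed with the product flux's lower bound
raised to a baseline (5e−4 in the toy scenario, the same order as a
producer's measured specific production rate) so the f_PH denominator is
non-zero; that floor is kept during every perturbation solve — the product
flux is free above the baseline, not free to collapse. Each reaction with
|v_ref| > 1e−9 and outside the exclusion lists is forced to v = k·v_ref
(equality; sign-preserving so a reverse flux −0.3 amplifies to −0.6). The
equality is the strict reading of a forced overexpression flux and keeps the
QP well-posed; `min_mode` gives the one-sided (at-least) variant. The
amplification extent is a free parameter of the method; the default k = 2
follows the fixed fold-amplification convention of flux-scanning strain
design, and a sweep over {1.5, 2, 3} is exercised in the tests to expose
sensitivity. Scored rows sort by f_PH descending, ties by reaction id;
infeasible targets trail. `count_targets` counts f_PH strictly above a
threshold (default 1: the natural reading of "better than wild type") split
by a configurable secondary-metabolism subsystem set.

## Conservation analysis

Top hit = lowest e-value, ties broken by higher bit score then smaller
subject id (order-independence). Conservation thresholds: identity ≥ 40 %
and coverage ≥ 50 % inclusive, e-value < 1e−5 strict — only the e-value
comparator is conventionally printed as strict, and "threshold of 40 %" is
read inclusively. Coverage is alignment_length / query_length from the
12-column format (gaps included), the only coverage measure that format
supports. Per-strain fractions are computed over all queries, which equals
the query-count-weighted mean of the strain's per-subsystem fractions.
Non-homolog classes are mutually exclusive and exhaustive: isozyme rescue is
reaction-based (another enzyme of a shared reaction is conserved), not
synteny-based, since synteny needs genome coordinates outside this scope;
"annotation-similar" is an externally curated input flag because no
text-similarity algorithm is specified by convention.

## Synthetic data

`make_toy_model` builds branched glucose→biomass networks with integer
branch yields 1..6; a yield-y branch splits a C6H12O6 unit into y precursor
and (6−y) byproduct CH2O units, so every interior reaction is exactly
elementally balanced — which is why non-integer yields are rejected.
`make_core_ascomycin_toy` is a fixed 17-reaction, 14-metabolite fixture:
glucose (uptake capped at 1.0) → lumped glycolysis (3 acetyl units per
glucose) → three precursor routes (ethylmalonyl chain, methylmalonyl route,
malonyl carboxylation) → product assembly and export, with a biomass sink
(2 acetyl + 1 malonyl per unit growth) and a maintenance drain forced at
0.05. The fixture emulates the precursor-competition structure of a real
producer — product chain vs growth vs maintenance — but none of a real
genome-scale model's scale (~2000 reactions), cofactor/energy bookkeeping,
or regulatory constraints; passing tests on it demonstrate the correctness
of the algorithms, not quantitative predictions for any real strain.
`make_hit_table` plants a passing top hit (identity 80, full-length,
e = 1e−50) for a deterministic index-prefix of queries and decoy hits that
fail all three thresholds simultaneously (identity 30, 30 % coverage,
e = 1e−3), so boundary semantics cannot perturb planted-fraction recovery;
fraction × n_queries must be an integer for exact recovery. All generators
are pure functions of their spec: byte-identical output on repeat.

`random_small_model` (3–6 reactions, finite bounds, 0 always feasible)
supplies the instances for solver-vs-oracle cross-checks. The brute-force
oracles enumerate all 3ⁿ bound-activity patterns: for the LP, fixing active
variables and solving the free part exactly when it has full rank visits
every vertex, and a bounded LP attains its max at a vertex; for the QP, the
optimum's own active set is among the patterns, so the minimum over feasible
candidates is the global minimum. Both are exponential by construction and
restricted to tiny instances.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 50 random
≤ 6-reaction instances per solver comparison, the 17-reaction curated toy
for scans (≤ 17 MOMA solves per scan), and 200-query hit tables. These sizes
make every check exhaustive (vertex/active-set enumeration) while the whole
suite completes in seconds.

## Known limitations

- Scores depend on the amplification factor k and the product baseline; both
  are reported parameters, not estimated quantities.
- The equality-amplification reading can declare saturated reactions
  infeasible where the one-sided variant would score them; both modes are
  provided.
- Gene–protein–reaction boolean logic is out of scope (gene lists are
  carried but not evaluated), as are flux-variability analysis, knockout
  design, and combinatorial multi-target scans.
- The TSV model dialect does not carry metabolite formulas or the product
  designation; JSON/SBML round-trip both.
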