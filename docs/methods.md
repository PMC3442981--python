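# Methods

## Model and problem setting

All computations operate on constraint-based stoichiometric models at steady
state: a metabolites × reactions matrix **S** (negative coefficient =
consumed), flux bounds per reaction, and a biomass pseudo-reaction as the
cellular objective. Flux balance analysis (FBA) is the LP

    max  c·v    s.t.   S·v = 0,   lb ≤ v ≤ ub.

The environment is not part of the model: it is a set of bound overrides
(`EnvironmentSpec`) applied at solve time. The sign convention is that
exchange flux is negative for uptake, so the standard condition used
throughout — glucose uptake 10, oxygen uptake 2, ATP maintenance at least
1 mmol·gDCW⁻¹·h⁻¹ — is the bound set `EX_glc_e ∈ [−10, 0]`,
`EX_o2_e ∈ [−2, 0]`, `ATPM ∈ [1, 1000]`. Maintenance is a lower bound, not
an equality, so excess ATP can always be dissipated. Effectively unbounded
directions use magnitude 1000, the genome-scale convention.

LPs are solved with HiGHS through `scipy.optimize.linprog`; the OptKnock
MILP with HiGHS through `scipy.optimize.milp`.

## Degenerate optima

FBA optima are usually degenerate faces, not points. Every reported
"production at maximal growth" therefore comes from a lexicographic solve
(`fix_and_optimize`): optimize growth, fix it within
`1e-9·max(1, |optimum|)`, then maximize (and separately minimize) the
product flux. Reporting both the max and the min makes weak coupling
visible: a design is growth-coupled only when the minimum at maximal growth
is positive.

Production envelopes constrain growth **from below** at each grid point
(biomass ≥ g over an equispaced grid from 0 to the maximum). At the right
edge this coincides with the lexicographic optimal face; at g = 0 it spans
the whole feasible flux cone of the target. The alternative convention
(fixing growth by equality) was rejected because a zero-growth equality
forbids the biomass drain from absorbing precursor flux and thereby reports
a spurious forced minimum on networks like PYRCORE, where the product
pathway is the only remaining sink of the branch-point metabolite.

## Gene–protein–reaction logic

GPR rules use case-insensitive `and`/`or`, parentheses and gene ids matching
`[A-Za-z0-9_.-]+`; the empty rule is always-on. `or` encodes isozymes, `and`
complex subunits; rules are taken literally (deleting one subunit of an
`and` complex suffices to disable it). Reaction-set → gene-set mapping
computes minimal hitting sets over the union of the targets' DNF conjuncts:
exhaustive inclusion-minimal enumeration up to 12 involved genes, and a
set-cover integer program with integer cuts beyond that (which then returns
all minimum-cardinality sets — a subset of the inclusion-minimal family;
instances that large do not occur in the shipped models). Each returned set
carries a side-effect report listing every other reaction it disables,
which is how shared genes (e.g. a decarboxylase driving both the ethanol
precursor and the acetoin condensation) are surfaced.

## OptKnock

The bilevel knockout-design program — outer: choose up to K reaction
knockouts maximizing product flux; inner: the cell maximizes growth — is
folded into one MILP by replacing the inner problem with its KKT
certificate: primal feasibility (`lb_j·y_j ≤ v_j ≤ ub_j·y_j` for candidates,
binary `y_j = 0` meaning knocked out), dual feasibility
(`Sᵀλ + μᵘᵇ − μˡᵇ = c_inner`), and the strong-duality equality
`c_inner·v = Σ_j (ub_j μᵘᵇ_j − lb_j μˡᵇ_j)`, in which the bilinear products
`y·μ` on candidate positions are linearized with auxiliary variables `z`
and big-M constraints (`z ≤ M·y`, `z ≤ μ`, `z ≥ μ − M(1−y)`). A budget row
`Σ(1−y) ≤ K` and a viability row `growth ≥ f_min` complete the program.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| big-M | 1000 | equals the default bound magnitude; must dominate every candidate bound (checked) |
| f_min | 5% of wild-type growth | the design literature's results are insensitive to the floor when predicted growth rates are large; configurable as fraction or absolute |
| MIP gap | 1e-6 | strategies are discrete; the gap only needs to separate distinct deletion sets |
| LP tolerances | 1e-9 | feasibility/optimality; growth fixing uses 1e-9·max(1, opt) |

Big-M truncates the dual space, and a too-small M can make the MILP lie
silently. Two defenses are built in: M is validated against the candidate
bounds, and **every** strategy the MILP returns is re-verified with
independent lexicographic LPs before being reported; a discrepancy beyond
1e-5 relative is logged and the LP values win. The MILP is solved cold
(no incumbent warm start; `scipy.optimize.milp` exposes none) — on the
desk-scale instances this costs milliseconds.

Candidate screening runs before the MILP and is plumbing, not part of the
formulation: exchange and transport reactions are never knockout targets,
nor are the biomass and maintenance pseudo-reactions; reactions whose
single knockout drops maximal growth below f_min (or kills feasibility) are
excluded as essential; blocked reactions (zero FVA range with no growth
requirement) are excluded as pointless. Exclusion reasons are logged per
reaction.

Alternative strategies are enumerated with integer cuts
(`Σ_{j∈D} y_j ≥ 1` for each previously returned deletion set D; the empty
set is cut by requiring at least one knockout). Because the budget can be
slack, the MILP may knock out reactions gratuitously; returned sets are
greedily pruned — a deletion is dropped if reactivating it preserves the
lexicographic target flux — which realizes the tie-break "fewer knockouts
first, then lexicographic ids" and makes output deterministic across
solvers. Distinct MILP solutions can prune to the same set; duplicates are
skipped, so no strategy is ever returned twice. Cuts on pruned sets also
suppress their supersets, which would prune back to duplicates anyway;
enumeration is therefore best-first over *distinct* pruned strategies
rather than over raw MILP solutions.

Transport detection is syntactic: metabolite ids end in `_<compartment>`
(`glc_e`, `pyr_c`), and a reaction is a transport when it spans ≥ 2
compartments and some compartment-stripped base species appears in more
than one of them. Exchanges touch exactly one metabolite. Reversibility is
representational only (bounds crossing zero); reactions are never split.

## Flux → mass yield

Yields in g product per g substrate are computed as
`Y = v_t·MW_t / (|v_s|·MW_s)` from the lexicographic maximum of the target
flux and the substrate uptake flux of the same solution. Molar masses are
package constants (2,3-butanediol 90.121, glucose 180.156, ethanol 46.068,
glycerol 92.094, acetate 60.052 g·mol⁻¹ — standard chemistry).

## The PYRCORE fixture

PYRCORE is a deliberately lumped two-compartment fermentation network:
glucose → 2 triose; triose + NAD⁺ + 2 ADP → pyruvate + NADH + 2 ATP;
a glycerol valve (triose + NADH → glycerol); pyruvate → acetaldehyde →
ethanol (NADH-consuming, isozyme rule `ADH1 or ADH3 or ADH5`); pyruvate +
acetaldehyde → acetoin → 2,3-butanediol (NADH-consuming); respiration
NADH + ½O₂ + 2 ADP → NAD⁺ + 2 ATP (P/O = 2); maintenance; biomass =
1 pyruvate + 3 ATP. Acetoin has deliberately **no** transport or exchange,
so the acetoin → butanediol fluxes are equal by mass balance and the hand
algebra is airtight. All optima of interest are small rationals, verified
by hand before being frozen into tests:

* wild type: growth 11 (ethanol 2, glycerol 7, respiration 4, butanediol 0;
  a unique vertex),
* ΔADH: growth 117/11, butanediol 10/11 (max = min: fully coupled),
  glycerol 83/11; zero-growth butanediol capacity 8,
* ΔADH + ΔRESP: growth 7, butanediol 2.

What the fixture emulates: the redox logic by which removing ethanol
formation redirects NADH (and carbon) into the glycerol and butanediol
branches, and the further fermentative forcing when respiration is removed.
What it does not emulate: genome-scale redundancy (thousands of internal
cycles and isoenzymes), compartmentalized cofactor pools, extracellular
acetoin accumulation, and any kinetic or regulatory effect. Passing tests
on PYRCORE therefore validate the *machinery* (LP/MILP correctness, GPR
logic, coupling detection), not quantitative predictions for real yeast;
quantitative reproduction requires the external iMM904 model via
`reproduce-table1`, which reports relative deviations rather than asserting
equality because the exact historical model encoding is not pinned down,
and which applies only the three published bound overrides on top of the
model's own exchange bounds (flagged in its output).

## Random model generator

`make_random_model` composes balanced templates under one seeded RNG:
substrate chain with a guaranteed ATP/NADH payoff step, optional extra
cofactor reductions, an isozyme-duplicated chain step (so at least one
chain reaction is individually dispensable), branch products drawing on
reduced cofactors (branch 0 always on the respiration-coupled pair, so the
design problem is never vacuous), a redox-free waste valve, one oxidase per
cofactor pair, maintenance and biomass. Every cofactor couple is conserved
by every reaction, so generated models are stoichiometrically consistent
and growth-feasible by construction — no repair step. Identical seeds give
byte-identical JSON serializations.

## Numerical choices and degenerate inputs

* Mass balance `‖S·v‖∞ ≤ 1e-6` is asserted on every optimal flux vector;
  strong duality of each LP is checked from the solver's multipliers.
* Infeasible/unbounded solves return a status, never an exception, except
  where an operation is meaningless without a base optimum (FVA, envelope),
  which raise.
* Zero maximal growth collapses the envelope to a single point with a
  warning; zero substrate flux makes mass yield a division error; an
  always-on GPR is "not gene-disableable" by definition and errors in the
  gene-mapping path while remaining deletable at the reaction level.
* The brute-force oracle refuses instances beyond 50,000 subsets.
* Ties everywhere break by size then lexicographic id, so results are
  reproducible across solver versions.

## Problem sizes

The shipped verification runs at desk scale: PYRCORE (23 reactions) for
all exact optima, knockout budgets 0–3, and 30 seeded random models
(roughly 25–35 reactions, ≤ 12 knockout candidates, K ≤ 3) for the
MILP-vs-enumeration equivalence, chosen so the exhaustive oracle remains
exact ground truth.
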