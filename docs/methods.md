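# Methods

## Model and scope

`comgapfill` implements community-level gap-filling as a mixed-integer
linear program over a compartmentalized community model. Each organism is a
namespaced compartment containing its model reactions and a set of
candidate reactions from a curated universal database, each gated by a
binary variable. Compartments interact only through a common metabolite
pool: per member and pool metabolite a reversible transfer reaction, per
pool metabolite one environment exchange bounded by the medium. The
objective minimizes the total number of candidates switched on subject to
per-compartment steady state, model bounds, binary-gated candidate bounds,
per-member biomass floors, and the pool balance
`−v_ex(i)^c + Σ_n w_n v_ex(i)^n = 0`.

Out of scope by design: thermodynamic (loopless) analysis, taxonomy- or
sequence-informed reaction scoring, dynamic community simulation, and
automated reconstruction of member models. Thermodynamically questionable
solutions are *flagged* (see Quality flags), not eliminated.

## Conventions and units

Fluxes are mmol·gDW⁻¹·h⁻¹ (any consistent unit system works; one ACT-3
style study uses d⁻¹). Uptake is negative, secretion positive (COBRA
convention). A transfer reaction carries −1 on the member's extracellular
species and +1 on the pool species. Unbounded bounds are replaced by a
global cap of ±1000 flux units (configurable); making the cap explicit is
what lets the quality flags define "near the infinite bounds" precisely.

Pool identity is the metabolite base id after stripping the `_e`
compartment suffix: members exchange a metabolite iff their extracellular
species share a base id. This assumes a shared (BiGG-style) namespace
across members and database; cross-namespace mapping is not attempted.
Whether members keep their original environment exchanges was an open
design point; they are **replaced** by pool transfers, so the pool is the
only route to the environment.

## Database curation

The candidate database is built from a raw reaction set by removing, in
order: biomass equations (explicit flag or case-insensitive "biomass"
id/name match), a user-supplied exclusion list (the stand-in for
"eukaryote-only" reactions, for which no algorithmic rule exists),
exchange reactions, and reactions that fail an exact element/charge
balance. Reactions of undetermined balance (a participant without a
formula) are excluded by default — conservative, since an unbalanced
candidate can act as a matter faucet — with `keep_undetermined=True` to
retain them and a whitelist for individually vetted reactions. Survivors
are reset to fully reversible (−cap, +cap): candidate directionality is
decided later by FVA, not by database annotations.

## FVA reduction

Before the MILP, every candidate gets an LP-exact flux range computed per
compartment under a deliberate over-approximation: the member's biomass
floor is dropped to zero (a gapped model cannot grow yet, so enforcing the
floor would be infeasible) and all pool transfers are opened to ±cap
(other members may in principle supply any pool metabolite). Because this
polytope contains every community-feasible flux assignment for the
compartment, deleting candidates whose range is identically zero and
tightening the rest to their range cannot remove or cut off any optimal
support — the pruned and unpruned MILPs have the same optimum, which the
test suite asserts on seeded communities. Whether the original study used
medium-constrained or fully open transfers during FVA is not stated; the
open choice is the sound one and is the default (`open_transfers=False`
exposes the medium-constrained mode, where widening the medium provably
never shrinks a range). Surviving bounds are rounded outward by the
zero-flux tolerance (1e-6) so FVA solver tolerance cannot render the MILP
spuriously infeasible.

## Solving and enumeration

The MILP is solved with HiGHS (via `scipy.optimize.milp`) at a relative
MIP gap of 0, i.e. to proven optimality. Binaries are rounded at 0.5 and
re-verified by fixing the support and re-solving the LP; the reported flux
vector is the minimum-total-flux point of that fixed-support LP, which
makes reported fluxes (and hence cross-feeding calls) deterministic rather
than an arbitrary vertex. Variables are ordered lexicographically by
member then reaction id, so repeated runs are bit-stable.

Alternative optima are enumerated solver-agnostically: after each solution
an integer cut `Σ_{(n,j) ∈ support} y_j^n ≤ |support| − 1` excludes that
added-reaction set and the MILP is re-solved. Solution identity is the
support (set of added reactions); flux degeneracy within one support is
not enumerated. With `allow_suboptimal` (default) the list may run past
the optimum ("k best"); otherwise enumeration stops at the first strictly
worse objective and reports `exhaustive_at_optimum`. On infeasible
communities the solver reports which members' floors fail even with the
full database active and all other floors relaxed.

When a solution is materialized into a standalone member model
(`apply_and_verify`), added reactions get the database's original
reversible bounds back — the FVA windows are context-dependent artifacts
of the reduction — while the verification FBA (member's maximal growth
with all supports fixed, which must reach its floor) keeps them.

The abundance-weighted variant multiplies member transfers in the pool
balance by relative abundances `w_n` (summing to 1). The original
formulation of this variant is in an appendix that is not part of the
article text; weighting the pool rows is the natural reading of correcting
the community mass balance when member fluxes are per-gDW, and is
implemented as such with the interpretation flagged here. With a single
member (`w = 1`) it reduces exactly to the unweighted problem, which is
tested.

## Synthetic study conditions

The fixture generator builds linear-chain metabolisms: member `n` imports
substrate `sub{n}` (medium supply −10 flux units, the conventional
glucose-scale uptake), converts it through a unit-stoichiometry chain of
3–5 steps, and drains the terminal metabolite through a biomass reaction
with a growth floor of 0.1 — an order of magnitude below the attainable
10, so gap-filling is forced by topology, not by tight capacity. Planted
gaps move chain reactions into the shared database; planted exchanges give
a donor a secretion pathway whose product a receiver can convert past its
own gap, making cross-feeding a genuine alternative to repair; decoy
candidates over disconnected metabolites pad the pool and must be FVA-
pruned. All metabolites carry the unit pseudo-formula "X" (charge 0), so
the networks pass curation by construction and fixture logic stays
decoupled from formula parsing. Every fixture ships its ground truth —
all minimum repair supports — computed at generation time by an exhaustive
oracle (breadth-first over support subsets by cardinality, plain LP
feasibility per subset, capped at 16 candidate pairs); randomized fixtures
keep `members × database` within that cap so the oracle stays exhaustive.

What the fixtures do *not* emulate: genome-scale redundancy (parallel
pathways, cofactor coupling), maintenance ATP demands, realistic
stoichiometric coefficients, and thermodynamically infeasible cycles.
Passing the synthetic suites therefore certifies the optimization
machinery — minimality, constraint satisfaction, pruning soundness,
enumeration completeness — not predictive biology on real
reconstructions, which depends on input model and database quality.

## Numerical choices

MIP gap 0; solver feasibility/integrality tolerances 1e-9 (HiGHS
defaults are at or below this); zero-flux threshold and steady-state
residual tolerance 1e-6; FVA outward rounding 1e-6. Growth floors must be
strictly positive — a zero floor makes gap-filling vacuous and is rejected
rather than silently satisfied. Medium default policy
`open_secretion_only` gives unlisted pool metabolites (0, +cap): they may
accumulate in the environment but not be imported; `closed` gives (0, 0).
Duplicate detection when grafting candidates onto a member uses the
reaction id and a scale/direction-invariant stoichiometry signature.

## Quality flags

Two heuristics mark solutions the original analysis would distrust:
fluxes at ≥90% of their own bound or above 100 flux units (`near_bound`),
and pairs of reactions in one compartment with proportional
stoichiometries and cancelling large fluxes (`cycle_pairs`) — the pairwise
signature of a thermodynamically infeasible cycle. Both thresholds are
qualitative in origin and configurable; the pair scan is deliberately not
a full loopless analysis. Cross-feeding edges require strictly
opposite-signed member transfers above 1e-6 for the same metabolite within
one solution; environment involvement does not cancel an edge.

## Problem sizes

The bundled suites use communities of 1–3 members with chains of 3–5
reactions and candidate pools of up to 12 reactions (the exhaustive-oracle
regime); the acceptance script sweeps 200 such seeded communities and
three canonical planted-gap designs. The reproduction script runs the
two-strain *E. coli* core community (72 metabolites, ~90 reactions per
member); genome-scale inputs are supported through the same API but their
reference data must be downloaded separately.

## Known limitations

* Candidate pools beyond the oracle cap are solved only by the MILP;
  optimality then rests on the solver's proof, not on cross-checking.
* The eukaryote-only exclusion list must be user-supplied; no curated list
  is bundled.
* Cycle detection is pairwise; longer infeasible loops pass unflagged.
* The abundance-weighted pool balance is an interpretation (see above).
* Enumerated "k best" lists depend on solver tie-breaking within an
  objective value; the support *sets* per objective value are complete
  when `exhaustive_at_optimum` is reported, but their relative order among
  equal objectives is not semantically meaningful.
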