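# Methods

## Steady-state model and linear programs

The core object is a compartmented stoichiometric network: metabolites with
elemental formula and charge, reactions with signed stoichiometry (negative
coefficients consume), finite flux bounds, an optional GPR rule and a kind
tag (metabolic, transport, exchange, biomass). Exchange fluxes use the
standard sign convention: negative flux is uptake, positive is secretion.
Infinite bounds are normalised on construction to a conventional big-M of
±1000 flux units (configurable at the big-M consumers); bounds on a
mmol·gDW⁻¹·h⁻¹-like basis-relative scale are assumed throughout.

All linear programs are of the form: optimise one flux subject to
`S·v = 0`, box bounds, and optionally extra inequality rows. They are
solved with HiGHS via `scipy.optimize.linprog`. There is no randomness in
the engine; given the same model and scenario the results are bit-stable.
Accepted solutions carry a steady-state residual `|S·v|_∞ ≤ 1e-6`
(surfaced on the result object, not hidden), and "zero flux" decisions use
an epsilon of 1e-6.

A single FBA solution is always one vertex of the optimal face and is
reported as such; FVA is the canonical description of what the optimum
does and does not pin down.

## Scenarios, basis constraints and diurnal phases

A scenario is a named growth condition: exchanges opened to stated uptakes
(all other exchanges are closed to uptake but left open for secretion), an
optional joint basis cap (one inequality row limiting the combined uptake
over a set of exchanges — e.g. a 100 mmol CO2 + bicarbonate basis), a
regulatory shutdown list (reactions fixed to zero in that condition, which
also covers cases like keeping only the aerobic cyclase system active), a
biomass reaction and an objective.

Diurnal physiology is imposed as bound modifications on named reaction
sets:

* **light**: glycogen and glycerol transport fixed to zero (no
  stored-carbon uptake); light and carbon-fixation reactions untouched;
* **dark**: light reactions and carbon-fixation reactions fixed to zero,
  CO2 transport restricted to efflux, stored-carbon uptake left open.

The published inequality forms of the phase constraints are not available
in the source text, so the package encodes the prose semantics above —
photosynthesis stores energy as glycogen in the light, the stored energy
is spent in the dark — as hard shut-offs. This is the one genuinely open
design point in the constraint set and is deliberately kept in a single
function (`apply_diurnal`).

## Knockouts and the essentiality screen

GPR rules are Boolean trees over gene ids with a distinguished `unknown`
leaf: an always-satisfiable placeholder for an unidentified complementing
gene product, which can never be knocked out. AND means a complex (all
subunits required), OR means isozymes, AND binds tighter than OR, and
parse∘print is the identity up to associativity flattening. A knockout
disables exactly the reactions whose rule evaluates false; the disabled
set is monotone in the knockout set.

The screen deletes one gene at a time, fixes the disabled reactions to
zero and re-maximises biomass. A mutant is called growing (G) when its
optimum reaches at least 10% of the wild-type optimum of the same
scenario; the threshold fraction is a parameter. Genes appearing in no
rule are G by construction and are not re-solved. Joining the in silico
verdict to an in vivo viability table gives the GG/GNG/NGG/NGNG
categories, with specificity = GG/(GG+NGG) and sensitivity =
NGNG/(NGNG+GNG); a zero denominator yields an undefined (None) metric
rather than 0. Rows flagged as incompletely segregated are dropped by the
table reader before the join.

## Yields

`compute_yield` maximises a product flux, optionally after fixing biomass
at a fraction (default 100%) of its scenario optimum, and divides by a
denominator flux: a named reaction (e.g. RuBisCO carboxylation for "per
mole carbon fixed" — carboxylation flux is used rather than gross carbon
uptake) or the total basis uptake. Because alternate optima make the
denominator vertex-dependent, the product flux is first pinned at its
optimum and the denominator is then *minimised* over the optimal face —
the maximum-yield reading of "per mole consumed", and deterministic. This
assumes an irreversible denominator reaction. An unreachable product
returns yield 0 together with a diagnostic naming the first blocked
precursor of the product reaction (probed with temporary-drain LPs).

## Quality control

**Balance linting.** Per reaction, the net imbalance of every element and
of charge is the stoichiometry-weighted sum of the metabolite formulas
and charges. Exchanges, demands and biomass drains are imbalanced by
construction and are skipped by design; reactions touching any metabolite
without formula or charge are skipped *with a reason* so a missing formula
can never masquerade as "balanced". Formulas are plain Hill-notation
element counts; polymeric or wildcard formulas (R groups, `(...)n`) are
rejected at parse time and surface as unparseable.

**Blocked metabolites.** A metabolite is blocked when it cannot turn over
in any steady-state flux distribution under the scenario's exchanges —
equivalently, when every reaction touching it has a zero FVA range. This
definition makes a dead-end metabolite (producers but no consumers)
blocked, as strict steady state demands, and it cascades to the upstream
reactions the dead-end silences. It is computed from one full FVA pass
(2 LPs per reaction) shared across all metabolites, rather than the
original binary MILP formulation — same verdicts, simpler trust story.
Because a defect's blockage cascades, planted-gap recovery is measured as
the *newly* blocked set relative to the pristine network.

**Gap filling.** Candidate reactions come from a user-supplied universal
pool (e.g. the union of two related reconstructions); the search is
iterative-deepening over subsets of size 1, 2, … up to a budget, returning
all minimal-cardinality addition sets in lexicographic id order. The
literature-corroboration step of published curation workflows is
inherently manual and is represented only by the accepted/rejected report.

**Infeasible loops.** With every exchange closed and all internal bounds
widened to the big-M box (irreversibility preserved), any reaction whose
attainable |flux| reaches 50% of big-M is riding an internal cycle that
would be unbounded in a naive formulation. Members are grouped into loops
by connected overlap of their witness flux supports; each group carries a
witness vector with `S·v = 0`, `v ≠ 0` and zero exchange flux. The member
threshold (0.5 × big-M) is configurable; the report is invariant under
scaling all bounds by a positive constant. Suggested repairs (make one
member irreversible / drop a redundant duplicate) are emitted as a list
and never auto-applied. A gap-fill proposal is rejected exactly when
applying it strictly enlarges the loop-member set.

## Synthetic fixtures

The generators produce networks whose correct answers are derived by hand
and recorded next to the model:

* **linear chains** (`make_linear_chain`): 1:1 conversion with one
  optional non-unit middle coefficient, so max biomass = uptake /
  coefficient; metabolites carry consistent CH2-unit formulas so the
  chains are balance-clean.
* **mini phototroph** (`make_mini_phototroph`): 16 reactions — photon
  exchange and transport, a light reaction (photon → ATP + NADPH), carbon
  fixation (CO2 + ATP + NADPH → triose), respiration (triose → CO2 +
  3 ATP), glycogen synthesis/breakdown, a nitrogenase-style H2 reaction
  (4 ATP + 2 NADPH → H2), and separate light/dark biomass equations.
  Default condition sizes, chosen once: 10 mmol CO2 basis (light),
  10 mmol glycogen basis (dark), photon cap 100 (light) and 20
  (subjective dark; some cap is required for a finite H2 optimum, exactly
  as photon availability bounds real phototrophs). Hand-derived optima:
  light biomass = basis; dark biomass = 3/4 of the glycogen basis (a
  quarter is respired for ATP); subjective-dark H2 = 3(P+G)/8 per basis —
  the LP exploits a carbon-fixation/respiration cycle that transhydrogenates
  NADPH into ATP, and the closed form accounts for it. Planted GPR ground
  truth: one essential light gene, a two-gene carbon-fixation complex
  (each subunit essential), an isozyme pair (individually dispensable) and
  one `or unknown` rule (never knockable). Currency metabolites carry no
  formulas, so the balance linter reports those reactions as skipped — the
  intended behaviour for abstract species.
* **branched networks + `plant_defect`**: a seeded trunk-plus-branch
  topology into which exactly one defect is planted — a reversed duplicate
  reaction (a forced two-cycle), the deletion of the branch's sole
  consumer (an orphaned intermediate), or a single stray proton in one
  reaction's stoichiometry (a +1 H and +1 charge imbalance). The explicit
  proton species exists so the imbalance is local to one reaction.
* **random toys** (`make_random_toy`): bounded random networks of at most
  8 reactions used for brute-force oracle comparison; all bounds finite so
  every LP is bounded and the vertex-enumeration oracle is exact.

All randomness flows from one explicit seeded `numpy` Generator; the same
seed reproduces a byte-identical serialised model. The fixtures emulate
topology, GPR structure, diurnal regulation and defect classes of real
reconstructions; they do not emulate genome-scale size, realistic biomass
compositions, cofactor diversity or compartment-specific proton balancing,
so green fixture tests certify the algorithms, not any particular
published model.

## Testing strategy and numerical choices

Two independent oracles anchor the suite: exhaustive vertex enumeration of
`{S·v = 0, l ≤ v ≤ u}` for LP optima and FVA ranges (agreement required to
1e-6), and truth-table evaluation (by text substitution into Python's own
boolean evaluator) for GPR rules. cobrapy with its GLPK stack provides a
second, library-level cross-check of FBA/FVA on the phototroph fixture; it
is never part of the implementation path. LP degeneracy and tie-breaking
are left to the solver; comparisons against published flux tables use 1%
relative tolerance since printed third decimals are solver-dependent.

The measured-vs-predicted flux-range comparison classifies each reaction
as `contained` (measured interval inside the model range), `under` (model
range strictly below), `over` (strictly above) or `partial`; unmapped
reactions are listed, never dropped.

Problem sizes in the default test run and acceptance script — 20–25
random toys for oracle equivalence, 50 planted-defect fixtures, 200
random GPR samples — were chosen as comfortably demonstrative for the
small fixture classes involved.

## Known limitations

* Genome-scale analyses (published reconstructions' yields, essentiality
  metrics, flux-range tables) run only when the SBML exports and the in
  vivo viability table are supplied under `data/external/`; these files
  are not redistributable with the package.
* No dynamic FBA across the light→dark transition, no thermodynamic
  (ΔG-based) constraints, no 13C-MFA estimation (measured intervals are
  inputs), no strain-design optimisation.
* The blocked-metabolite scan and gap-fill search solve O(reactions) and
  O(pool^k) LPs respectively; both are sized for curation-scale questions,
  not for exhaustive genome-scale sweeps with large addition budgets.
* Yield denominators assume an irreversible denominator reaction.
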