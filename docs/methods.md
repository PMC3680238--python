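# Methods

## Model and scope

`fluxscreen` operates on steady-state stoichiometric models: a matrix
S (metabolites × reactions), flux bounds lb ≤ v ≤ ub in mmol/gDCW/h,
boolean gene–protein–reaction (GPR) rules, one biomass objective
reaction (flux = specific growth rate, 1/h) and one product exchange
whose flux is the screened production rate. Exchange reactions are
written `met → ∅`, so export is positive and substrate uptake is a
negative lower bound; a measured uptake of 3.472 mmol/gDCW/h becomes
`lb = −3.472` on the corresponding exchange. Product rates quoted in
μmol/gDCW/h are converted to mmol at ingestion (1.61 μmol → 0.00161)
and the conversion is recorded in the constraint set's notes.

Kinetics, thermodynamics, regulation and expression are out of scope:
a knockout is a closed reaction, an overexpression is a pinned flux.

## Solvers and numerical choices

* **FBA / pFBA / FVA** use `scipy.optimize.linprog` (HiGHS). HiGHS is
  deterministic, so identical inputs give identical flux vectors.
* **MOMA** solves `min ‖v − v_ref‖²` with OSQP at `eps_abs = eps_rel =
  1e-10`, solution polishing on, and iteration-based rho adaptation
  (interval 50) so repeated solves are bit-identical. Returned fluxes
  are clipped to the box at 1e-9 to absorb solver round-off.
* Tolerances: steady-state residual ‖S·v‖∞ ≤ 1e-6 on every optimal
  state; bound violation ≤ 1e-9; a reference flux counts as "non-zero"
  (overexpression candidacy) above 1e-6.
* pFBA pins the objective at its FBA optimum with a relative slack of
  1e-10 (absorbing LP round-off while keeping the objective within
  1e-9 of the optimum) and minimises Σ w_j |v_j| via the standard
  forward/reverse split, returning net fluxes. The weights (default
  all 1) exist so robustness analyses can perturb the parsimony
  tie-break and generate alternate parsimonious references; on the
  bundled fixtures the parsimonious optimum is a unique vertex, and
  screen rankings are verified identical across perturbed-weight
  references — the operational meaning of "the prediction is unique
  although the FBA flux distribution is not".
* An infeasible perturbed polytope is reported as a *lethal*
  perturbation (status, not exception), so screens continue across
  candidates. An unbounded FBA signals a missing exchange bound and is
  likewise reported in the status.

## Screen semantics

* **Reference.** All screens measure mutants against the pFBA
  reference of the unperturbed model. The enforced product lower
  bound (the measured production rate) applies to the reference only
  and is dropped from mutant solves by default
  (`ScreenOptions.product_bound_in_mutant` restores it): forcing a
  mutant to secrete at the wild-type rate would prejudge the question
  the screen asks.
* **Knockouts** map genes to reactions through the GPR rules: a
  reaction is closed iff its rule evaluates false with the deleted
  genes absent and all others present. Isoenzymes (OR) survive single
  deletions; complex subunits (AND) do not. Reactions with empty rules
  (spontaneous, or lumped multi-gene routes) are never closed.
* **Amplification** is an equality pin at k·v_ref (sign-preserving;
  default k = 2). A raised-lower-bound variant is available behind
  `ScreenOptions.amplification_as_lower_bound` for sensitivity
  analysis. Pins exceeding the reaction's bounds are clipped and
  flagged `bound_limited`. Zero-reference candidates are skipped —
  there is nothing to amplify.
* **Ranking.** Knockout (and combined-with-filter) results rank by
  product flux among mutants with growth ≥ `growth_min`; the
  overexpression screen ranks by f_PH without a viability filter,
  reporting growth alongside. Sorting is stable with ties broken by
  higher growth, then lexicographic perturbation spec; lethal entries
  are listed last, unranked. `growth_min` defaults to 0.04 1/h — a
  viability floor of the order of 80% of a slow-growing producer's
  wild-type rate; on the toy fixtures, whose growth is two orders of
  magnitude faster, analyses use half the wild-type growth as the
  equivalent floor.
* **f_PH** is implemented exactly as the product of the two
  dimensionless ratios, (μ_mut/μ_wt)·(v_prod,mut/v_prod,wt). Prose
  descriptions of this score sometimes call it a "ratio" of the two
  quantities; the product form is the displayed definition and is what
  is implemented. It requires strictly positive wild-type biomass and
  product fluxes, which is why the reference must be solved with the
  measured production rate enforced.
* **Combined screen** applies knockout zeros and the amplification pin
  (at k × the *wild-type* reference flux) simultaneously in one MOMA
  solve against the wild-type reference. Pinning at k × the
  knockout-mutant's flux instead would require a second reference per
  knockout; the wild-type convention keeps all combinations comparable
  on one scale. Combinations whose pinned reaction is disabled by the
  knockout itself are skipped with a logged reason.
* Gene-level overexpression calls map a gene to its GPR-associated
  reactions; each reaction is screened separately and the gene scores
  the maximum (`gene_level_scores`).

## The synthetic fixtures

The generator emulates the structural situation the screens assume: a
producer whose product competes with growth for a cofactor (NADPH) and
a precursor, under a bounded carbon supply.

The **core fixture** (22 reactions, 21 metabolites, 14 genes) contains
a carbon uptake (bound 10 mmol/gDCW/h), a lumped glycolysis (2
pyruvate + 2 NADH per carbon unit), a capacity-limited
pentose-phosphate-like path (1 precursor + 2 NADPH, cap 4), a lumped
TCA/respiration energy system, and:

* **planted knockout target `gdh` (GDH)** — an NADPH-consuming
  amino-acid route, capacity 6, alongside a costlier NADH+ATP bypass
  with no single knockable gene. Deleting `gdh` reroutes amino-acid
  synthesis through the bypass at a modest ATP cost and frees up to
  6 mmol/gDCW/h of NADPH, which MOMA pushes partly into the product
  (the only other NADPH consumer besides a one-way dissipation valve);
* **planted overexpression target `dahp` (PSUP)** — the committed
  precursor-supply step feeding both biomass and product. Its
  reference flux is dominated by biomass demand, so a 2-fold pin
  creates a precursor surplus far larger than the wild-type product
  flux; a capacity-limited overflow secretion (cap 1) absorbs some of
  it, and the rest is available to the product if — and only if —
  NADPH allows. This NADPH coupling makes the combined
  knockout+amplification super-additive in f_PH by construction;
* a secondary target `ppc` draining precursor back to pyruvate, and
  decoy genes (transporters, isoenzyme pairs, an idle
  transhydrogenase valve) that the screens must rank below the
  planted targets.

Elemental balance uses abstract conserved tags (C carbon, R redox
units, A/P adenylate/phosphate, M/Q nicotinamide moieties) so the
structural audit proves every internal reaction exactly balanced
without curated chemistry. The biomass reaction consumes 3 amino-acid
units, 0.3 precursor and 10 ATP per unit growth.

The fixture's FBA optimum is hand-derivable: eliminating the
metabolite balances leaves growth limited by the NADPH amination
capacity `a_max = min(drain cap, 2 × PPP cap)` with
μ* = (14u + a_max)/37, and μ* = 7u/17 in the unconstrained
energy-limited regime (`core_growth_closed_form`; 146/37 ≈ 3.946 1/h
at the defaults, verified against the LP in the tests). The reference
condition adds a product demand of 0.2 mmol/gDCW/h — the toy analogue
of constraining the model with a measured production rate (2% of
carbon uptake, mirroring the minor-product regime).

**Random variants** (`make_random_model`) redraw, deterministically
from a seed: pathway lengths (0–2 extra chain steps in glycolysis and
the product path), the NADPH stoichiometry of product synthesis
({1, 2}), the bypass NADH cost ({1, 2}), isoenzyme assignments
(probability 0.3 per internal gene), and the two planted capacities.
The drain capacity is drawn U[3, 10] and the supply capacity U[4, 10]
rather than the generic U[1, 10] used for other magnitudes: below
those floors the planted roles are *false* in the generated network (a
drain below ≈3 frees less NADPH than its bypass costs in ATP, so its
deletion lowers product; a supply cap below twice the reference flux
clips the amplification pin to a no-op), and a generator must not
label a non-target as truth. Feasibility (growth > 0 under the
reference condition) is guaranteed by rejection sampling with a
50-draw budget.

What the fixtures do **not** emulate: genome-scale redundancy (hundreds
of alternative routes that soften MOMA's response), realistic
biomass composition, by-product chemistry, or μ in the 0.05 1/h range
of slow-growing actinomycetes (toy growth is O(1) because the network
is shallow). Passing the recovery tests therefore shows the screens
identify the planted mechanism when it is present, not that any
particular real-organism prediction is correct.

## Verification strategy

Every solver is checked against an implementation-independent oracle:
FBA against exhaustive vertex enumeration on random ≤8-reaction
polytopes and against cobrapy/GLPK on the core fixture; pFBA against
cobrapy's pFBA flux sum and against random-weight alternates; MOMA
against dense grid search on a 1-degree-of-freedom toy (including the
analytic optimum), against 1000 random feasible points per fixture,
and via the relax-to-zero monotonicity of the distance. GPR evaluation
is property-tested against direct truth-table evaluation on random
rules of ≤ 6 genes. Screens are compared with brute-force enumeration
of every candidate perturbation on the core fixture, and
planted-target recovery is measured on 20 freshly drawn random
fixtures (top-3 threshold 18/20).

## Known limitations

* MOMA uses the unweighted Euclidean metric over all reactions,
  exchanges included; no flux scaling is applied, so the metric is
  dominated by high-flux pathways.
* The overexpression screen models enzyme amplification as an exact
  flux multiple, ignoring the expression-to-flux gap; multi-gene
  simultaneous overexpression is deliberately unsupported (the
  amplification factors would not be experimentally commensurable).
* Pairwise knockout screens are quadratic in the gene list and default
  to a user-supplied list; all-pairs on a genome-scale model is
  opt-in.
* SBML I/O targets Level 3 + fbc version 2 on write (Level 2 read is
  supported with reversibility-derived default bounds ±1000); the
  product-reaction designation is stored as a second, inactive fbc
  objective named `product_rate`, a convention this package defines.
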