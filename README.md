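# fluxscreen

Constraint-based strain-design screens for secondary-metabolite
overproducers: flux balance analysis (FBA), parsimonious FBA, flux
variability analysis, MOMA, and the three in-silico screens used to
pick metabolic-engineering targets — gene knockout, reaction-flux
amplification ("overexpression"), and combined knockout +
overexpression — over genome-scale or synthetic metabolic models.

## The problem

An industrial producer of a polyketide (or any growth-uncoupled
product) diverts only a sliver of its carbon to the product; most flux
serves growth. Given a stoichiometric model of the strain's metabolism
with measured uptake and secretion rates, which single gene should be
deleted, and which reaction amplified, to push more flux into the
product without killing growth?

`fluxscreen` answers this with the classic constraint-based recipe:

1. **Wild-type reference.** FBA maximises the biomass flux μ over the
   steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}, with the measured
   rates as exchange bounds (uptake = negative lower bound; the
   measured product secretion rate as the product exchange's lower
   bound). Because the FBA optimum is degenerate, the reference flux
   distribution is fixed by **parsimonious FBA**: among optima,
   minimise Σ|v|. This makes every downstream prediction reproducible.
2. **Knockout screen.** For each candidate gene (or gene pair), the
   reactions whose gene–protein–reaction rules fail are closed and the
   mutant flux state is predicted by **MOMA** — the quadratic program
   `min Σ (v − v_ref)²` over the perturbed polytope, i.e. the feasible
   state closest to the parent strain. Candidates are ranked by
   predicted product flux among mutants whose growth clears a
   viability floor.
3. **Overexpression screen.** Each reaction carrying non-zero
   reference flux is pinned at k × its reference value (default
   2-fold) and re-solved by MOMA. Candidates are ranked by the
   overproduction score

   f_PH = f_biomass × f_product = (μ_mut / μ_wt) × (v_prod,mut / v_prod,wt)

   which rewards product gain that does not come at the price of
   growth.
4. **Combined screen.** A knockout set and one amplification pin
   applied in a single MOMA solve, ranked by f_PH.

A synthetic-network generator provides small, fully mass-balanced
fixtures with *planted* targets — an NADPH drain whose deletion frees
cofactor for the product, and a precursor-supply step whose
amplification floods the product pathway — so the entire pipeline is
testable end to end against brute-force oracles.

## Worked example

```python
import fluxscreen as fs

model = fs.make_core_fixture()             # 22-reaction toy producer
conditions = fs.core_conditions()          # uptake 10, product demand 0.2 mmol/gDCW/h

wild = fs.solve_fba(model, conditions)
ref = fs.solve_pfba(model, conditions)
print(f"wild-type growth: {wild.objective_value:.4f} 1/h, "
      f"product flux: {ref.value('EX_fk'):.3f} mmol/gDCW/h")

opts = fs.ScreenOptions(growth_min=0.5 * ref.objective_value)
ko = fs.knockout_screen(model, conditions, ref, options=opts)
for r in ko[:3]:
    print(f"KO  rank {r.rank}: {r.perturbation.spec_string():8s} "
          f"growth {r.growth:.3f}  product {r.product_flux:.3f}  f_PH {r.f_ph:.2f}")

oe = fs.overexpression_screen(model, conditions, ref, options=opts)
top = oe[0]
print(f"OE  rank 1: {top.perturbation.spec_string():10s} "
      f"growth {top.growth:.3f}  product {top.product_flux:.3f}  f_PH {top.f_ph:.2f}")

combo = fs.combined_screen(model, conditions, ref,
                           knockout_sets=[("gdh",)], oe_candidates=["PSUP"],
                           options=opts)
both = combo[0]
print(f"KO+OE:      {both.perturbation.spec_string():16s} "
      f"growth {both.growth:.3f}  product {both.product_flux:.3f}  f_PH {both.f_ph:.2f}")
```

prints

```
wild-type growth: 3.8378 1/h, product flux: 0.200 mmol/gDCW/h
KO  rank 1: ko:gdh   growth 3.196  product 0.900  f_PH 3.75
KO  rank 2: ko:chot  growth 3.838  product 0.200  f_PH 1.00
KO  rank 3: ko:glyA  growth 3.838  product 0.200  f_PH 1.00
OE  rank 1: oe:PSUPx2  growth 3.238  product 0.731  f_PH 3.08
KO+OE:      ko:gdh|oe:PSUPx2 growth 2.974  product 1.184  f_PH 4.59
```

Reading it: deleting the NADPH-consuming amination route `gdh` costs
17% of growth but multiplies product flux 4.5-fold, because the
cofactor the drain consumed now reduces the polyketide chain instead —
and the screen finds it at rank 1 without being told. Amplifying the
committed precursor-supply step `PSUP` 2-fold is the best
overexpression (f_PH 3.08), and doing both at once is super-additive
(f_PH 4.59 > either alone): the knockout frees the NADPH that the
amplified precursor supply needs.

The same screens run from the shell:

```
fluxscreen make-toy --out toy/
fluxscreen ko-screen --model toy/model.tsv --constraints toy/conditions.yaml \
    --growth-min 1.9 --out results/
```

Models load from SBML (`--format sbml`) or the tabular dialect; real
production conditions (a measured carbon uptake, capped amino-acid
uptakes, a measured product rate) are built with
`fluxscreen.production_conditions`, with the exchange-role mapping
always supplied explicitly.

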