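"""Synthetic metabolic-network fixtures with planted strain-design targets.

The fixtures emulate, at toy scale, the structural features the screens
exploit in a real secondary-metabolite producer:

* a bounded carbon uptake feeding a glycolysis-like path (ATP + NADH)
  and a pentose-phosphate-like path (NADPH + a biosynthetic precursor);
* a biomass reaction consuming amino-acid equivalents, a precursor and
  ATP — its flux is the specific growth rate;
* a product ("polyketide") synthesis reaction consuming the precursor,
  NADPH and ATP, with an export step whose flux is the screened
  product rate;
* a planted **knockout target**: an NADPH-consuming amino-acid route
  (``gdh``, glutamate-dehydrogenase analogue) competing with product
  synthesis for NADPH, with an NADH-using bypass so its deletion is
  viable — deleting it frees NADPH for the product, mirroring how
  deleting a cellular NADPH drain raises polyketide flux;
* a planted **overexpression target**: the committed precursor-supply
  step (``dahp`` analogue) that also feeds biomass, so that pinning its
  flux at twice the reference creates a precursor surplus only the
  product pathway can absorb;
* a second knockout target (``ppc`` analogue) draining the precursor
  pool back into lower glycolysis.

Elemental balance uses abstract conserved tags (C carbon units,
R redox/electron-pair units, plus A/P adenylate-phosphate and M/Q
nicotinamide carrier moieties) so :func:`~fluxscreen.model.validate_model`
certifies every internal reaction exactly, without curated chemistry.

Closed-form optimum of the core fixture
---------------------------------------
With uptake bound :math:`u` and no product demand, growth is
energy-limited: eliminating the metabolite balances leaves
``10·mu = 14·u − 24·mu``, i.e. ``mu* = 7 u / 17`` (≈ 4.11765 1/h at
u = 10), attained on a face where the glycolysis/PPP split is free —
parsimonious FBA resolves the split (maximal PPP, transhydrogenase
idle, precursor overflow through the ``ppc`` drain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConstraintSet, DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "PlantedTruth",
    "GenerationError",
    "make_core_fixture",
    "core_conditions",
    "make_random_model",
    "random_spec",
    "planted_truth",
    "core_growth_closed_form",
]

def core_growth_closed_form(uptake: float, drain_cap: float = 6.0,
                            ppp_cap: float = 4.0) -> float:
    """Closed-form FBA optimum of the core fixture at zero product demand.

    The NADPH amination route is limited to ``a_max = min(drain_cap,
    2*ppp_cap)``; the residual amino-acid demand pays one extra ATP per
    unit through the bypass, giving ``mu* = (14 u + a_max) / 37``.  When
    the route is unconstrained (``a_max >= 3 mu*``) growth is purely
    energy-limited with ``mu* = 7 u / 17``."""
    mu_energy = 7.0 * uptake / 17.0
    a_max = min(drain_cap, 2.0 * ppp_cap)
    if a_max >= 3.0 * mu_energy:
        return mu_energy
    return (14.0 * uptake + a_max) / 37.0


class GenerationError(RuntimeError):
    """Random generation failed to produce a feasible model."""


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the random fixture generator.

    ``drain_strength`` caps the planted NADPH-drain reaction,
    ``precursor_bottleneck`` caps the planted supply step (both in
    mmol/gDCW/h, drawn U[1, 10] by :func:`random_spec`).
    ``n_linear_pathways`` bounds the extra chain reactions inserted
    into the glycolysis and product paths (pathway-length variation).
    ``product_demand`` is the enforced minimum product-export flux of
    the reference condition (the toy analogue of a measured production
    rate).  Identical specs (same seed) yield identical models.
    """

    n_linear_pathways: int = 2
    cofactor_coupling: bool = True
    drain_strength: float = 6.0
    precursor_bottleneck: float = DEFAULT_BOUND
    biomass_coeffs: dict = field(default_factory=lambda: {"aa": 3.0, "cho": 0.3})
    uptake_bound: float = 10.0
    product_demand: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.uptake_bound <= 0 or self.drain_strength <= 0 \
                or self.precursor_bottleneck <= 0:
            raise ValueError("capacities must be strictly positive")
        if any(v <= 0 for v in self.biomass_coeffs.values()):
            raise ValueError("biomass coefficients must be strictly positive")


@dataclass(frozen=True)
class PlantedTruth:
    """Identifiers of the planted targets, for oracle comparison."""

    knockout_gene: str
    knockout_reaction: str
    secondary_knockout_gene: str
    overexpression_reaction: str
    overexpression_gene: str
    synergy: tuple[tuple[str, ...], str]  # (knockout genes, amplified reaction)


_CORE_TRUTH = PlantedTruth(
    knockout_gene="gdh",
    knockout_reaction="GDH",
    secondary_knockout_gene="ppc",
    overexpression_reaction="PSUP",
    overexpression_gene="dahp",
    synergy=(("gdh",), "PSUP"),
)


def _build(
    uptake_bound: float,
    gly_chain: int = 0,
    product_chain: int = 0,
    nadph_per_product: float = 2.0,
    drain_nadh_cost: float = 1.0,
    drain_cap: float = 6.0,
    supply_cap: float = DEFAULT_BOUND,
    ppp_cap: float = 4.0,
    overflow_cap: float = 1.0,
    biomass_aa: float = 3.0,
    biomass_cho: float = 0.3,
    isoenzymes: frozenset[str] = frozenset({"gly"}),
) -> MetabolicModel:
    """Assemble the (possibly randomised) core topology.

    ``gly_chain``/``product_chain`` insert that many extra
    isomerisation steps; ``nadph_per_product`` of 0 decouples the
    product from the NADPH pool (``cofactor_coupling=False``).
    """
    w = nadph_per_product
    d = drain_nadh_cost
    fk_formula = f"C9R{6 + w:g}"

    mets = [
        Metabolite("glc_e", "carbon source (external)", "C6R6", 0, "e"),
        Metabolite("glc_c", "carbon source", "C6R6", 0, "c"),
        Metabolite("pyr_c", "pyruvate-like node", "C3R2", 0, "c"),
        Metabolite("pre_c", "PPP-derived precursor", "C6R4", 0, "c"),
        Metabolite("cho_c", "committed product precursor", "C6R4", 0, "c"),
        Metabolite("aa_c", "amino-acid equivalent", "C3R3", 0, "c"),
        Metabolite("fk_c", "product (polyketide)", fk_formula, 0, "c"),
        Metabolite("fk_e", "product (external)", fk_formula, 0, "e"),
        Metabolite("nad_c", "NAD+", "M", 0, "c"),
        Metabolite("nadh_c", "NADH", "MR", 0, "c"),
        Metabolite("nadp_c", "NADP+", "Q", 0, "c"),
        Metabolite("nadph_c", "NADPH", "QR", 0, "c"),
        Metabolite("adp_c", "ADP", "A", 0, "c"),
        Metabolite("atp_c", "ATP", "AP", 0, "c"),
        Metabolite("pi_c", "phosphate", "P", 0, "c"),
        Metabolite("cho_e", "committed precursor (external)", "C6R4", 0, "e"),
        Metabolite("was_c", "oxidised carbon waste", "C3", 0, "c"),
        Metabolite("was_e", "oxidised carbon waste (external)", "C3", 0, "e"),
        Metabolite("red_c", "spent reducing equivalent", "R", 0, "c"),
        Metabolite("red_e", "spent reducing equivalent (external)", "R", 0, "e"),
        Metabolite("bio_e", "biomass", None, None, "e"),
    ]
    for i in range(gly_chain):
        mets.append(Metabolite(f"gly{i}_c", f"glycolytic intermediate {i}", "C6R6", 0, "c"))
    for i in range(product_chain):
        mets.append(Metabolite(f"cho{i}_c", f"product-path intermediate {i}", "C6R4", 0, "c"))

    def rule(gene: str) -> str:
        return f"{gene} or {gene}_iso" if gene in isoenzymes else gene

    rxns: list[Reaction] = [
        Reaction("EX_glc", {"glc_e": -1}, -uptake_bound, DEFAULT_BOUND,
                 "carbon exchange", is_exchange=True),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, DEFAULT_BOUND,
                 "carbon uptake transport", rule("gtr")),
    ]
    # glycolysis-like lumped path, optionally lengthened
    gly_in = "glc_c"
    for i in range(gly_chain):
        rxns.append(Reaction(f"GLY{i}", {gly_in: -1, f"gly{i}_c": 1},
                             0, DEFAULT_BOUND, f"glycolysis step {i}", rule(f"glyc{i}")))
        gly_in = f"gly{i}_c"
    rxns += [
        Reaction("GLY", {gly_in: -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2},
                 0, DEFAULT_BOUND, "glycolysis (lumped)", "glyA or glyB"),
        Reaction("PPP", {"glc_c": -1, "nadp_c": -2, "pre_c": 1, "nadph_c": 2},
                 0, ppp_cap, "pentose phosphate path (lumped)", rule("zwf")),
        Reaction("TCA", {"pyr_c": -1, "nad_c": -2, "adp_c": -1, "pi_c": -1,
                         "was_c": 1, "nadh_c": 2, "atp_c": 1},
                 0, DEFAULT_BOUND, "TCA cycle (lumped)", "tcaA and tcaB"),
        Reaction("RESP", {"nadh_c": -1, "adp_c": -2, "pi_c": -2,
                          "nad_c": 1, "atp_c": 2, "red_c": 1},
                 0, DEFAULT_BOUND, "oxidative phosphorylation", rule("resp")),
        # planted knockout target: NADPH-consuming amino-acid route
        Reaction("GDH", {"pyr_c": -1, "nadph_c": -1, "aa_c": 1, "nadp_c": 1},
                 0, drain_cap, "NADPH amination route (drain)", "gdh"),
        # viable bypass: NADH- and ATP-dependent, strictly costlier than
        # the NADPH route; modelled as a lumped aggregate of alternative
        # amination routes, so it carries no single knockable gene
        Reaction(
            "GDH2",
            {k: v for k, v in {
                "pyr_c": -1.0, "nadh_c": -d, "atp_c": -1.0,
                "aa_c": 1.0, "nad_c": d, "adp_c": 1.0, "pi_c": 1.0,
                "red_c": d - 1.0,
            }.items() if v != 0},
            0, DEFAULT_BOUND, "NADH amination bypass (lumped)"),
        # secondary knockout target: precursor drain to lower glycolysis
        Reaction("PPC", {"pre_c": -1, "pyr_c": 2},
                 0, DEFAULT_BOUND, "precursor overflow to pyruvate", "ppc"),
        # planted overexpression target: committed precursor-supply step
        Reaction("PSUP", {"pre_c": -1, "cho_c": 1},
                 0, supply_cap, "committed precursor supply", "dahp"),
        # one-way NADPH -> NADH dissipation (soluble-transhydrogenase-like):
        # the network's only relief valve for excess NADPH
        Reaction("PNT", {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1},
                 0, DEFAULT_BOUND, "NADPH dissipation valve", rule("pnt")),
    ]
    # product path, optionally lengthened before synthesis
    fks_cho = "cho_c"
    for i in range(product_chain):
        rxns.append(Reaction(f"PCH{i}", {fks_cho: -1, f"cho{i}_c": 1},
                             0, DEFAULT_BOUND, f"product path step {i}", rule(f"pch{i}")))
        fks_cho = f"cho{i}_c"
    fks_stoich = {fks_cho: -1.0, "pyr_c": -1.0, "atp_c": -1.0,
                  "fk_c": 1.0, "adp_c": 1.0, "pi_c": 1.0}
    if w:
        fks_stoich.update({"nadph_c": -w, "nadp_c": w})
    rxns += [
        Reaction("FKS", fks_stoich, 0, DEFAULT_BOUND,
                 "product synthase (lumped)", rule("fks")),
        Reaction("FKt", {"fk_c": -1, "fk_e": 1}, 0, DEFAULT_BOUND,
                 "product export transport", rule("fkt")),
        # capacity-limited precursor overflow secretion: amplified supply
        # is not fully forced into the product unless cofactors allow it
        Reaction("CHOt", {"cho_c": -1, "cho_e": 1}, 0, overflow_cap,
                 "precursor overflow secretion", rule("chot")),
        Reaction("EX_cho", {"cho_e": -1}, 0, DEFAULT_BOUND,
                 "precursor exchange", is_exchange=True),
        Reaction("EX_fk", {"fk_e": -1}, 0, DEFAULT_BOUND,
                 "product exchange", is_exchange=True),
        Reaction("BIO", {"aa_c": -biomass_aa, "cho_c": -biomass_cho,
                         "atp_c": -10, "adp_c": 10, "pi_c": 10, "bio_e": 1},
                 0, DEFAULT_BOUND, "biomass synthesis"),
        Reaction("EX_bio", {"bio_e": -1}, 0, DEFAULT_BOUND,
                 "biomass sink", is_exchange=True),
        Reaction("WASt", {"was_c": -1, "was_e": 1}, 0, DEFAULT_BOUND,
                 "waste export"),
        Reaction("EX_was", {"was_e": -1}, 0, DEFAULT_BOUND,
                 "waste exchange", is_exchange=True),
        Reaction("REDt", {"red_c": -1, "red_e": 1}, 0, DEFAULT_BOUND,
                 "spent-redox export"),
        Reaction("EX_red", {"red_e": -1}, 0, DEFAULT_BOUND,
                 "spent-redox exchange", is_exchange=True),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id="BIO",
        product_id="EX_fk",
        name="toy-core",
    )


def make_core_fixture(uptake_bound: float = 10.0) -> MetabolicModel:
    """The fixed 20-reaction core fixture (see module docstring)."""
    return _build(uptake_bound)


def core_conditions(
    uptake_bound: float = 10.0, product_demand: float = 0.2
) -> ConstraintSet:
    """Reference growth condition for the core fixture.

    Carbon uptake bounded at ``uptake_bound`` (negative lower bound on
    the exchange) and the measured product rate enforced as the lower
    bound of the product exchange — the toy analogue of constraining a
    model with observed consumption/production rates.
    """
    return ConstraintSet(
        {
            "EX_glc": (-uptake_bound, DEFAULT_BOUND),
            "EX_fk": (product_demand, DEFAULT_BOUND),
        },
        notes=f"toy reference condition: uptake {uptake_bound}, "
              f"product demand {product_demand} mmol/gDCW/h",
    )


def random_spec(seed: int) -> ToySpec:
    """Draw a ToySpec from the documented ranges.

    Capacities are drawn from ranges in which the planted roles are
    actually true in the generated network.  The supply-step capacity
    is U[4, 10]: the planted overexpression target needs headroom above
    twice its reference flux (≈ 1.4 mmol/gDCW/h), otherwise the
    amplification pin clips at the capacity.  The drain capacity is
    U[3, 10]: below ≈ 3 mmol/gDCW/h the ATP cost of rerouting amino-acid
    synthesis outweighs the freed NADPH and deleting the drain no longer
    raises product flux — a weak drain is not a knockout target.
    """
    rng = np.random.default_rng(seed)
    return ToySpec(
        n_linear_pathways=int(rng.integers(0, 3)),
        cofactor_coupling=True,
        drain_strength=float(rng.uniform(3.0, 10.0)),
        precursor_bottleneck=float(rng.uniform(4.0, 10.0)),
        uptake_bound=10.0,
        product_demand=0.2,
        seed=seed,
    )


def _generate(spec: ToySpec, rng: np.random.Generator) -> MetabolicModel:
    internal_genes = {"gtr", "zwf", "resp", "pnt", "fks", "fkt", "gly"}
    iso = frozenset(g for g in internal_genes if rng.random() < 0.3) | {"gly"}
    return _build(
        uptake_bound=spec.uptake_bound,
        gly_chain=int(rng.integers(0, spec.n_linear_pathways + 1)),
        product_chain=int(rng.integers(0, spec.n_linear_pathways + 1)),
        nadph_per_product=float(rng.choice([1.0, 2.0])) if spec.cofactor_coupling else 0.0,
        drain_nadh_cost=float(rng.choice([1.0, 2.0])),
        drain_cap=spec.drain_strength,
        supply_cap=spec.precursor_bottleneck,
        biomass_aa=spec.biomass_coeffs.get("aa", 3.0),
        biomass_cho=spec.biomass_coeffs.get("cho", 1.0),
        isoenzymes=iso,
    )


def make_random_model(spec: ToySpec, max_attempts: int = 50) -> MetabolicModel:
    """A randomised variant of the core topology, guaranteed feasible.

    Pathway lengths, cofactor stoichiometry and isoenzyme assignments
    are drawn deterministically from ``spec.seed``; candidates failing
    the feasibility contract (reference growth > 0 with the product
    demand enforced) are rejected and redrawn, up to ``max_attempts``.
    """
    from .optimize import solve_fba  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    conditions = core_conditions(spec.uptake_bound, spec.product_demand)
    for _ in range(max_attempts):
        model = _generate(spec, rng)
        state = solve_fba(model, conditions)
        if state.optimal and state.objective_value > 1e-6:
            return model
    raise GenerationError(f"no feasible model in {max_attempts} draws for {spec}")


def planted_truth(spec: ToySpec | None = None) -> PlantedTruth:
    """Planted target identifiers (identical across core and random
    variants — the randomisation preserves the planted roles)."""
    return _CORE_TRUTH
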