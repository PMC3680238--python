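"""In-silico strain-design screens.

Three screens drive target identification for overproducing a
growth-uncoupled product (e.g. a polyketide secondary metabolite):

* **Knockout screen** — delete each candidate gene (or unordered gene
  pair), disable the reactions whose gene rules fail, and predict the
  mutant's fluxes by MOMA against the parsimonious wild-type reference.
  Candidates are ranked by predicted product flux among mutants whose
  growth stays above a viability floor (default 0.04 1/h).
* **Overexpression screen** — amplify each reaction carrying non-zero
  reference flux to ``k`` times its reference value (default 2-fold),
  pin it there, re-solve MOMA, and rank by the overproduction score

  .. math::

      f_{PH} = f_{biomass} \\times f_{product}
             = \\frac{v_{bio}^{mut}}{v_{bio}^{wt}}
               \\times \\frac{v_{prod}^{mut}}{v_{prod}^{wt}}

  which rewards mutants that raise product flux without paying for it
  in growth.  No growth filter is applied here; growth is reported.
* **Combined screen** — apply a knockout set and one amplification pin
  simultaneously in a single MOMA solve against the wild-type
  reference, ranked by :math:`f_{PH}`.

The wild-type reference must carry strictly positive biomass and
product fluxes (enforce the measured production rate as a lower bound
on the product exchange), otherwise the ratios are undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

from .model import ConstraintSet, MetabolicModel, knockout_bounds
from .optimize import (
    NONZERO_FLUX,
    FluxState,
    SolverOptions,
    solve_moma,
)

__all__ = [
    "Perturbation",
    "ScreenResult",
    "ScreenOptions",
    "compute_fph",
    "knockout_screen",
    "overexpression_screen",
    "combined_screen",
    "rank_targets",
    "gene_level_scores",
]

logger = logging.getLogger(__name__)

MMOL_TO_UMOL = 1000.0


@dataclass(frozen=True)
class Perturbation:
    """A strain manipulation: knockout, overexpression, or both."""

    kind: str  # "knockout" | "overexpression" | "combined"
    knockout_genes: frozenset[str] = frozenset()
    amplified_reaction: str | None = None
    amplification_factor: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "knockout_genes", frozenset(self.knockout_genes))
        has_ko = bool(self.knockout_genes)
        has_oe = self.amplified_reaction is not None
        valid = {
            "knockout": has_ko and not has_oe,
            "overexpression": has_oe and not has_ko,
            "combined": has_ko and has_oe,
        }
        if self.kind not in valid:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not valid[self.kind]:
            raise ValueError(
                f"perturbation fields inconsistent with kind={self.kind!r}"
            )
        if has_oe and (self.amplification_factor is None or self.amplification_factor <= 0):
            raise ValueError("amplification_factor must be > 0")

    def spec_string(self) -> str:
        parts = []
        if self.knockout_genes:
            parts.append("ko:" + ",".join(sorted(self.knockout_genes)))
        if self.amplified_reaction is not None:
            parts.append(f"oe:{self.amplified_reaction}x{self.amplification_factor:g}")
        return "|".join(parts)


@dataclass
class ScreenResult:
    """Outcome of simulating one perturbation.

    ``product_flux`` is in mmol/gDCW/h (``product_flux_umol`` converts);
    ``growth`` in 1/h.  ``status`` is "lethal" when the perturbed
    polytope is empty.  ``rank`` is assigned by :func:`rank_targets`
    (``None`` for lethal or filtered-out entries).
    """

    perturbation: Perturbation
    status: str
    growth: float = float("nan")
    product_flux: float = float("nan")
    f_biomass: float = float("nan")
    f_product: float = float("nan")
    f_ph: float = float("nan")
    passes_growth_filter: bool = False
    bound_limited: bool = False
    rank: int | None = None
    note: str = ""

    @property
    def product_flux_umol(self) -> float:
        return self.product_flux * MMOL_TO_UMOL


@dataclass
class ScreenOptions:
    """Shared screen configuration.

    ``product_bound_in_mutant=False`` (default) removes the enforced
    product lower bound from mutant solves so the measured production
    rate constrains only the wild-type reference; set ``True`` to keep
    it imposed on mutants as well.  ``amplification_as_lower_bound``
    switches the overexpression pin from an equality at ``k·v_ref`` to
    a raised lower bound (sensitivity-analysis variant).
    """

    k: float = 2.0
    growth_min: float = 0.04
    product_bound_in_mutant: bool = False
    amplification_as_lower_bound: bool = False
    nonzero_flux: float = NONZERO_FLUX
    solver: SolverOptions = field(default_factory=SolverOptions)


def compute_fph(
    wild: FluxState,
    mutant: FluxState,
    objective: str,
    product: str,
) -> tuple[float, float, float]:
    """The overproduction score and its two factors.

    Returns ``(f_biomass, f_product, f_ph)`` with
    ``f_ph = f_biomass * f_product``.  Requires strictly positive
    wild-type biomass and product fluxes — a zero wild-type product
    flux means the reference was solved without the measured production
    rate as a product lower bound, and the score is undefined.
    """
    if not wild.optimal:
        raise ValueError("wild-type reference is not optimal")
    wb, wp = wild.value(objective), wild.value(product)
    if wb <= 0:
        raise ValueError(f"wild-type biomass flux must be > 0 (got {wb:g})")
    if wp <= 0:
        raise ValueError(
            f"wild-type product flux must be > 0 (got {wp:g}); enforce the "
            "measured production rate as the product exchange lower bound"
        )
    f_biomass = mutant.value(objective) / wb
    f_product = mutant.value(product) / wp
    return f_biomass, f_product, f_biomass * f_product


def _mutant_base_constraints(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    options: ScreenOptions,
) -> ConstraintSet:
    base = constraints or ConstraintSet()
    if options.product_bound_in_mutant or model.product_id is None:
        return base
    return base.without(model.product_id)


def _simulate(
    model: MetabolicModel,
    base: ConstraintSet,
    perturbation: Perturbation,
    v_ref: FluxState,
    options: ScreenOptions,
) -> ScreenResult:
    """One perturbed MOMA solve → ScreenResult (unranked)."""
    overrides = [base]
    bound_limited = False
    if perturbation.knockout_genes:
        overrides.append(knockout_bounds(model, perturbation.knockout_genes))
    if perturbation.amplified_reaction is not None:
        rid = perturbation.amplified_reaction
        rxn = model.reactions[rid]
        target = perturbation.amplification_factor * v_ref.value(rid)
        clipped = min(max(target, rxn.lower_bound), rxn.upper_bound)
        if clipped != target:
            bound_limited = True
        if options.amplification_as_lower_bound:
            pin = (clipped, rxn.upper_bound) if target >= 0 else (rxn.lower_bound, clipped)
        else:
            pin = (clipped, clipped)
        overrides.append(ConstraintSet({rid: pin}, notes=f"pin {rid}"))
    merged = overrides[0].merge(*overrides[1:])
    state = solve_moma(model, merged, v_ref, options.solver)
    if not state.optimal:
        result = ScreenResult(perturbation=perturbation, status="lethal",
                              bound_limited=bound_limited, note=state.solver_meta)
    else:
        f_b, f_p, f_ph = compute_fph(
            v_ref, state, model.objective_id, model.product_id
        )
        growth = state.value(model.objective_id)
        result = ScreenResult(
            perturbation=perturbation,
            status="optimal",
            growth=growth,
            product_flux=state.value(model.product_id),
            f_biomass=f_b,
            f_product=f_p,
            f_ph=f_ph,
            passes_growth_filter=growth >= options.growth_min,
            bound_limited=bound_limited,
        )
    logger.info(
        "screen %s status=%s growth=%.6g product=%.6g f_ph=%.6g",
        perturbation.spec_string(), result.status, result.growth,
        result.product_flux, result.f_ph,
    )
    return result


def knockout_screen(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    v_ref: FluxState,
    genes: Iterable[str] | str = "all",
    pairs: bool = False,
    options: ScreenOptions = ScreenOptions(),
) -> list[ScreenResult]:
    """Single (or pairwise) gene-deletion screen ranked by product flux.

    ``genes="all"`` screens every gene in the model; pass an explicit
    list to restrict (recommended for pairwise screens, which are
    quadratic in the list length).  Mutants below ``growth_min`` keep
    their records but are unranked; lethal deletions are listed last.
    """
    if model.product_id is None:
        raise ValueError("knockout screen requires model.product_id")
    gene_list = sorted(model.genes) if isinstance(genes, str) else sorted(set(genes))
    candidates = (
        [frozenset(p) for p in combinations(gene_list, 2)]
        if pairs
        else [frozenset([g]) for g in gene_list]
    )
    base = _mutant_base_constraints(model, constraints, options)
    results = [
        _simulate(model, base, Perturbation("knockout", knockout_genes=ko),
                  v_ref, options)
        for ko in candidates
    ]
    return rank_targets(results, by="product_flux", growth_min=options.growth_min)


def overexpression_screen(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    v_ref: FluxState,
    candidates: Iterable[str] | str = "all",
    options: ScreenOptions = ScreenOptions(),
) -> list[ScreenResult]:
    """Flux-amplification screen ranked by f_PH.

    Each candidate reaction with non-zero reference flux is pinned at
    ``k`` times its reference value (sign-preserving; clipped to the
    reaction's bounds, flagged ``bound_limited`` when clipped) and the
    mutant solved by MOMA.  Zero-flux candidates are skipped — with no
    reference flux there is nothing to amplify.
    """
    if model.product_id is None:
        raise ValueError("overexpression screen requires model.product_id")
    rids = model.reaction_ids if isinstance(candidates, str) else list(candidates)
    results = []
    base = _mutant_base_constraints(model, constraints, options)
    for rid in rids:
        if abs(v_ref.value(rid)) <= options.nonzero_flux:
            logger.info("skip %s: reference flux %.3g below threshold",
                        rid, v_ref.value(rid))
            continue
        pert = Perturbation(
            "overexpression", amplified_reaction=rid,
            amplification_factor=options.k,
        )
        results.append(_simulate(model, base, pert, v_ref, options))
    # f_PH alone decides the overexpression ranking; no viability filter
    return rank_targets(results, by="f_ph", growth_min=None)


def combined_screen(
    model: MetabolicModel,
    constraints: ConstraintSet | None,
    v_ref: FluxState,
    knockout_sets: Sequence[Iterable[str]],
    oe_candidates: Iterable[str],
    options: ScreenOptions = ScreenOptions(),
) -> list[ScreenResult]:
    """Knockout + single-overexpression combinations, ranked by f_PH.

    Both perturbations are applied at once (knockout zeros plus the
    amplification pin at ``k`` × the *wild-type* reference flux) and
    solved with a single MOMA against the wild-type reference.
    Combinations whose pinned reaction is itself disabled by the
    knockout are skipped.
    """
    if model.product_id is None:
        raise ValueError("combined screen requires model.product_id")
    base = _mutant_base_constraints(model, constraints, options)
    results = []
    for ko in knockout_sets:
        ko = frozenset(ko)
        disabled = knockout_bounds(model, ko).bound_overrides if ko else {}
        for rid in oe_candidates:
            if rid in disabled:
                logger.info("skip %s + %s: amplified reaction disabled by knockout",
                            sorted(ko), rid)
                continue
            if abs(v_ref.value(rid)) <= options.nonzero_flux:
                logger.info("skip %s: reference flux below threshold", rid)
                continue
            kind = "combined" if ko else "overexpression"
            pert = Perturbation(
                kind, knockout_genes=ko, amplified_reaction=rid,
                amplification_factor=options.k,
            )
            results.append(_simulate(model, base, pert, v_ref, options))
    return rank_targets(results, by="f_ph", growth_min=options.growth_min)


def rank_targets(
    results: Sequence[ScreenResult],
    by: str = "product_flux",
    growth_min: float | None = 0.04,
) -> list[ScreenResult]:
    """Assign ranks: score descending, ties by higher growth then spec.

    Stable: equal (score, growth, spec) keep input order.  Entries that
    are lethal or fail the growth filter keep their records with
    ``rank=None``; lethal entries sort last.
    """
    if by not in ("product_flux", "f_ph"):
        raise ValueError(f"cannot rank by {by!r}")

    def eligible(r: ScreenResult) -> bool:
        if r.status != "optimal":
            return False
        return growth_min is None or r.growth >= growth_min

    ranked = sorted(
        (r for r in results if eligible(r)),
        key=lambda r: (-getattr(r, by), -r.growth, r.perturbation.spec_string()),
    )
    filtered = [r for r in results if not eligible(r) and r.status == "optimal"]
    lethal = [r for r in results if r.status != "optimal"]
    out = []
    for i, r in enumerate(ranked, start=1):
        out.append(replace_rank(r, i))
    out.extend(replace_rank(r, None) for r in filtered)
    out.extend(replace_rank(r, None) for r in lethal)
    return out


def replace_rank(result: ScreenResult, rank: int | None) -> ScreenResult:
    return replace(result, rank=rank)


def gene_level_scores(
    model: MetabolicModel, results: Sequence[ScreenResult]
) -> dict[str, ScreenResult]:
    """Aggregate reaction-level overexpression results to genes.

    A gene's score is the best (highest f_PH) result among the
    reactions its gene rule participates in — the amplification
    algorithm operates on reaction fluxes, while engineering targets
    are named by gene.
    """
    best: dict[str, ScreenResult] = {}
    for result in results:
        rid = result.perturbation.amplified_reaction
        if rid is None or result.status != "optimal":
            continue
        for gene in model.reactions[rid].genes:
            if gene not in best or result.f_ph > best[gene].f_ph:
                best[gene] = result
    return best
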