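"""Data model for constraint-based metabolic networks.

The central object is :class:`MetabolicModel`: a steady-state
stoichiometric network of :class:`Metabolite` and :class:`Reaction`
objects with flux bounds (mmol/gDCW/h), gene rules, a biomass objective
and an optional product (e.g. secondary-metabolite export) reaction.
:class:`ConstraintSet` carries named bound overrides — growth-medium
uptake limits, measured production rates, knockouts, amplification pins —
that are applied on top of a model without mutating it.

Sign conventions
----------------
Exchange reactions are written ``met ->`` (one metabolite, coefficient
−1): a positive flux exports the metabolite and substrate uptake is a
*negative* flux, so a measured uptake of 3.472 mmol/gDCW/h becomes a
lower bound of −3.472 on the corresponding exchange.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .gpr import Gpr, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConstraintSet",
    "ValidationReport",
    "ModelError",
    "DEFAULT_BOUND",
    "parse_formula",
    "knockout_bounds",
    "validate_model",
]

#: magnitude used for "unconstrained" flux bounds, mmol/gDCW/h
DEFAULT_BOUND = 1000.0

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or constraint sets."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element→count.

    Elements are one capital letter plus an optional lowercase letter;
    a missing count means 1.  Abstract one-letter conservation tags
    (as used by the synthetic fixtures) parse the same way.
    """
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _ELEMENT.match(formula, pos)
        if m is None or m.start() != pos:
            raise ModelError(f"malformed formula {formula!r} at position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    return counts


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.formula is not None:
            parse_formula(self.formula)  # validates

    @property
    def elements(self) -> dict[str, int] | None:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds and a gene rule.

    ``stoichiometry`` maps metabolite id → signed coefficient
    (negative = consumed).  ``is_exchange`` marks boundary
    pseudo-reactions, which carry exactly one metabolite.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_rule: str = ""
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if self.is_exchange:
            if len(self.stoichiometry) != 1:
                raise ModelError(
                    f"exchange reaction {self.id} must have exactly one metabolite"
                )
        elif not self.stoichiometry:
            raise ModelError(f"reaction {self.id} has empty stoichiometry")
        # parse eagerly so malformed rules fail at construction
        object.__setattr__(self, "_gpr", parse_gpr(self.gene_rule))

    @property
    def gpr(self) -> Gpr:
        return self._gpr  # type: ignore[attr-defined]

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


class MetabolicModel:
    """An immutable-by-convention genome-scale (or toy) metabolic model.

    Parameters
    ----------
    metabolites, reactions:
        The network members, in a stable order (this order defines the
        rows/columns of the stoichiometric matrix).
    objective_id:
        Reaction whose flux is maximised by flux balance analysis,
        conventionally the biomass reaction (flux in 1/h).
    product_id:
        Exchange/transport reaction whose flux is the screened product
        rate, e.g. FK506 export.  Optional.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_id: str | None = None,
        product_id: str | None = None,
        name: str = "",
    ):
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id!r}")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
            self.reactions[rxn.id] = rxn
        for label, rid in (("objective", objective_id), ("product", product_id)):
            if rid is not None and rid not in self.reactions:
                raise ModelError(f"{label} reaction {rid!r} not in model")
        self.objective_id = objective_id
        self.product_id = product_id
        self.name = name

    # -- structure ---------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        """Union of all gene identifiers over all gene rules."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return frozenset(out)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S with one row per metabolite, one column per reaction."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(
        self, constraints: "ConstraintSet | None" = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(lb, ub) vectors in reaction order, with overrides applied."""
        lb = np.array([r.lower_bound for r in self.reactions.values()], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], dtype=float)
        if constraints is not None:
            constraints.validate(self)
            index = {rid: j for j, rid in enumerate(self.reactions)}
            for rid, (lo, hi) in constraints.bound_overrides.items():
                j = index[rid]
                lb[j], ub[j] = lo, hi
        return lb, ub

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self, **overrides) -> "MetabolicModel":
        kwargs = dict(
            metabolites=list(self.metabolites.values()),
            reactions=list(self.reactions.values()),
            objective_id=self.objective_id,
            product_id=self.product_id,
            name=self.name,
        )
        kwargs.update(overrides)
        return MetabolicModel(**kwargs)

    def with_reaction_bounds(self, rid: str, lower: float, upper: float) -> "MetabolicModel":
        """A copy with one reaction's bounds replaced (convenience for tests)."""
        reactions = [
            replace(r, lower_bound=lower, upper_bound=upper) if r.id == rid else r
            for r in self.reactions.values()
        ]
        return self.copy(reactions=reactions)

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.name or '(unnamed)'}: "
            f"{len(self.metabolites)} metabolites, {len(self.reactions)} reactions, "
            f"{len(self.genes)} genes>"
        )


@dataclass
class ConstraintSet:
    """Named flux-bound overrides, in mmol/gDCW/h.

    Overrides replace both bounds of the named reaction.  Constraint
    sets are composable with ``merge``; later overrides win.  ``notes``
    records provenance, including unit conversions (product rates are
    often reported in μmol/gDCW/h and converted at ingestion).
    """

    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        for rid, (lo, hi) in self.bound_overrides.items():
            if lo > hi:
                raise ModelError(
                    f"override for {rid!r}: lower bound {lo} exceeds upper bound {hi}"
                )

    def validate(self, model: MetabolicModel) -> None:
        missing = [rid for rid in self.bound_overrides if rid not in model.reactions]
        if missing:
            raise ModelError(
                f"constraint overrides reference unknown reactions: {missing}"
            )

    def merge(self, *others: "ConstraintSet") -> "ConstraintSet":
        overrides = dict(self.bound_overrides)
        notes = [self.notes] if self.notes else []
        for other in others:
            overrides.update(other.bound_overrides)
            if other.notes:
                notes.append(other.notes)
        return ConstraintSet(overrides, "; ".join(notes))

    def without(self, *reaction_ids: str) -> "ConstraintSet":
        overrides = {
            rid: b for rid, b in self.bound_overrides.items() if rid not in reaction_ids
        }
        return ConstraintSet(overrides, self.notes)

    def __len__(self) -> int:
        return len(self.bound_overrides)


def knockout_bounds(model: MetabolicModel, genes: Iterable[str]) -> ConstraintSet:
    """Bound overrides implementing a gene knockout.

    Every reaction whose gene rule evaluates to ``False`` with the given
    genes deleted (all other genes present) is pinned to zero flux.
    Reactions with an empty rule are never disabled.  Genes absent from
    the model are ignored with a warning, so screens over externally
    supplied gene lists degrade gracefully.
    """
    genes = set(genes)
    if not genes:
        raise ModelError("knockout gene set must be non-empty")
    unknown = genes - set(model.genes)
    if unknown:
        warnings.warn(
            f"knockout genes not present in any gene rule: {sorted(unknown)}",
            stacklevel=2,
        )
    overrides = {}
    for rxn in model.reactions.values():
        if rxn.gpr and not rxn.gpr.evaluate(knocked_out=genes):
            overrides[rxn.id] = (0.0, 0.0)
    return ConstraintSet(overrides, notes=f"knockout {','.join(sorted(genes))}")


@dataclass
class ValidationReport:
    """Advisory structural audit of a model; never mutates it.

    ``mass_unbalanced`` lists reactions whose available formulas do not
    balance, with the per-element imbalance (positive = net creation).
    Reactions involving a metabolite without a formula are skipped and
    listed in ``not_assessed``.  Exchange reactions are exempt by
    definition (they move mass across the boundary).
    """

    mass_unbalanced: dict[str, dict[str, float]] = field(default_factory=dict)
    charge_unbalanced: dict[str, float] = field(default_factory=dict)
    dead_end_metabolites: list[str] = field(default_factory=list)
    bound_violations: list[str] = field(default_factory=list)
    not_assessed: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.mass_unbalanced
            or self.charge_unbalanced
            or self.dead_end_metabolites
            or self.bound_violations
        )

    def summary(self) -> str:
        lines = [
            f"mass-unbalanced reactions: {len(self.mass_unbalanced)}",
            f"charge-unbalanced reactions: {len(self.charge_unbalanced)}",
            f"dead-end metabolites: {len(self.dead_end_metabolites)}",
            f"bound violations: {len(self.bound_violations)}",
            f"not assessed (missing formulas): {len(self.not_assessed)}",
        ]
        for rid, imb in self.mass_unbalanced.items():
            lines.append(f"  {rid}: " + ", ".join(f"{el}{v:+g}" for el, v in imb.items()))
        for met in self.dead_end_metabolites:
            lines.append(f"  dead end: {met}")
        return "\n".join(lines)


def validate_model(model: MetabolicModel, tol: float = 1e-9) -> ValidationReport:
    """Audit elemental/charge balance, dead ends and bound sanity."""
    report = ValidationReport()
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        elements = {}
        charge = 0.0
        assessable = True
        charge_assessable = True
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.elements is None:
                assessable = False
            else:
                for el, n in met.elements.items():
                    elements[el] = elements.get(el, 0.0) + coef * n
            if met.charge is None:
                charge_assessable = False
            else:
                charge += coef * met.charge
        if not assessable:
            report.not_assessed.append(rxn.id)
        else:
            imbalance = {el: v for el, v in elements.items() if abs(v) > tol}
            if imbalance:
                report.mass_unbalanced[rxn.id] = imbalance
        if charge_assessable and abs(charge) > tol:
            report.charge_unbalanced[rxn.id] = charge

    # dead ends: metabolite only producible or only consumable, counting
    # reversible reactions as both directions
    producers: dict[str, int] = {m: 0 for m in model.metabolites}
    consumers: dict[str, int] = {m: 0 for m in model.metabolites}
    for rxn in model.reactions.values():
        for met_id, coef in rxn.stoichiometry.items():
            forward = rxn.upper_bound > tol
            backward = rxn.lower_bound < -tol
            if coef > 0:
                producers[met_id] += forward
                consumers[met_id] += backward
            elif coef < 0:
                consumers[met_id] += forward
                producers[met_id] += backward
    for met_id in model.metabolites:
        if bool(producers[met_id]) != bool(consumers[met_id]):
            report.dead_end_metabolites.append(met_id)

    for rxn in model.reactions.values():
        if not (math.isfinite(rxn.lower_bound) and math.isfinite(rxn.upper_bound)):
            report.bound_violations.append(
                f"{rxn.id}: non-finite bounds ({rxn.lower_bound}, {rxn.upper_bound})"
            )
    return report
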