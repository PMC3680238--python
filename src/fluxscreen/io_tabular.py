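"""Plain-text (TSV) model and result I/O.

The tabular model dialect is one row per reaction with a header line::

    id<TAB>name<TAB>equation<TAB>lb<TAB>ub<TAB>genes<TAB>subsystem

Equations use ``->`` for irreversible and ``<=>`` for reversible
reactions, ``+``-separated terms with optional numeric coefficients,
and a ``[e]``-style compartment suffix on species (unsuffixed species
default to the cytosol, ``c``).  One side may be empty, which marks an
exchange reaction.  Column names are remappable via :class:`Dialect`
because supplementary model spreadsheets rarely agree on a layout.

Lines starting with ``#`` before the header carry optional metadata::

    # model: core
    # objective: BIO
    # product: EX_fk

Missing bounds default to (0, 1000) for irreversible and (−1000, 1000)
for reversible reactions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "Dialect",
    "TabularParseError",
    "parse_equation",
    "format_equation",
    "load_tabular_model",
    "write_tabular_model",
    "write_results_tsv",
    "read_results_tsv",
    "RESULT_COLUMNS",
]

_SPECIES = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+?)(?:\[(\w+)\])?$")
_ARROWS = ("<=>", "<->", "->")


class TabularParseError(ModelError):
    """Malformed tabular model file; message names the offending line."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for the tabular reaction-list format."""

    id: str = "id"
    name: str = "name"
    equation: str = "equation"
    lb: str = "lb"
    ub: str = "ub"
    genes: str = "genes"
    subsystem: str = "subsystem"
    default_compartment: str = "c"


def _parse_side(side: str, where: str) -> list[tuple[float, str, str | None]]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for chunk in side.split(" + "):
        chunk = chunk.strip()
        m = _SPECIES.match(chunk)
        if m is None or not chunk:
            raise TabularParseError(f"{where}: cannot parse species term {chunk!r}")
        coef, species, comp = m.groups()
        terms.append((float(coef) if coef else 1.0, species, comp))
    return terms


def parse_equation(
    equation: str, default_compartment: str = "c", where: str = "equation"
) -> tuple[dict[tuple[str, str], float], bool]:
    """Parse one equation string.

    Returns ``(stoichiometry, reversible)`` where stoichiometry maps
    ``(species, compartment)`` to the signed coefficient.
    """
    for arrow in _ARROWS:
        if arrow in equation:
            reversible = arrow != "->"
            left, right = equation.split(arrow, 1)
            break
    else:
        raise TabularParseError(f"{where}: no reaction arrow in {equation!r}")
    stoich: dict[tuple[str, str], float] = {}
    for sign, side in ((-1.0, left), (1.0, right)):
        for coef, species, comp in _parse_side(side, where):
            key = (species, comp or default_compartment)
            stoich[key] = stoich.get(key, 0.0) + sign * coef
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise TabularParseError(f"{where}: equation {equation!r} has no net species")
    return stoich, reversible


def format_equation(rxn: Reaction, model: MetabolicModel, default_compartment: str = "c") -> str:
    def term(met_id: str, coef: float) -> str:
        met = model.metabolites[met_id]
        species = met_id
        suffix = ""
        if met.compartment != default_compartment:
            # non-default compartments use the "<species>_<comp>" id
            # convention; equations render the [comp] suffix instead
            suffix = f"[{met.compartment}]"
            if species.endswith(f"_{met.compartment}"):
                species = species[: -(len(met.compartment) + 1)]
        coef_txt = "" if coef == 1.0 else f"{coef:g} "
        return f"{coef_txt}{species}{suffix}"

    left = " + ".join(term(m, -c) for m, c in rxn.stoichiometry.items() if c < 0)
    right = " + ".join(term(m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.lower_bound < 0 else "->"
    return f"{left} {arrow} {right}".strip()


def _met_id(species: str, comp: str, default_compartment: str) -> str:
    return species if comp == default_compartment else f"{species}_{comp}"


def load_tabular_model(
    path: str | Path,
    dialect: Dialect = Dialect(),
    objective_id: str | None = None,
    product_id: str | None = None,
) -> MetabolicModel:
    """Read a tabular reaction list into a validated :class:`MetabolicModel`.

    Metabolites are created on first mention; formulas/charges are not
    part of this dialect (use SBML for fully annotated models).
    Reactions with exactly one metabolite are flagged as exchanges.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = 0
    with path.open() as fh:
        raw = fh.readlines()
    body_start = 0
    for i, line in enumerate(raw):
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            header_line = i + 1
            break
    reader = csv.DictReader(raw[body_start:], delimiter="\t")
    if reader.fieldnames is None or dialect.id not in reader.fieldnames:
        raise TabularParseError(
            f"{path.name}: missing required column {dialect.id!r} in header"
        )
    if dialect.equation not in reader.fieldnames:
        raise TabularParseError(
            f"{path.name}: missing required column {dialect.equation!r} in header"
        )

    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    seen: set[str] = set()
    for offset, row in enumerate(reader):
        lineno = header_line + 1 + offset
        where = f"{path.name}:{lineno}"
        rid = (row.get(dialect.id) or "").strip()
        if not rid:
            raise TabularParseError(f"{where}: empty reaction id")
        if rid in seen:
            raise ModelError(f"{where}: duplicate reaction id {rid!r}")
        seen.add(rid)
        equation = (row.get(dialect.equation) or "").strip()
        stoich_raw, reversible = parse_equation(
            equation, dialect.default_compartment, where
        )
        stoich: dict[str, float] = {}
        for (species, comp), coef in stoich_raw.items():
            mid = _met_id(species, comp, dialect.default_compartment)
            if mid not in metabolites:
                metabolites[mid] = Metabolite(id=mid, name=species, compartment=comp)
            stoich[mid] = coef
        lb_txt = (row.get(dialect.lb) or "").strip()
        ub_txt = (row.get(dialect.ub) or "").strip()
        lb = float(lb_txt) if lb_txt else (-DEFAULT_BOUND if reversible else 0.0)
        ub = float(ub_txt) if ub_txt else DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=rid,
                name=(row.get(dialect.name) or "").strip(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=(row.get(dialect.genes) or "").strip(),
                subsystem=(row.get(dialect.subsystem) or "").strip(),
                is_exchange=len(stoich) == 1,
            )
        )
    return MetabolicModel(
        metabolites=list(metabolites.values()),
        reactions=reactions,
        objective_id=objective_id or meta.get("objective") or None,
        product_id=product_id or meta.get("product") or None,
        name=meta.get("model", path.stem),
    )


def write_tabular_model(
    model: MetabolicModel, path: str | Path, dialect: Dialect = Dialect()
) -> None:
    """Write the model in the tabular dialect (lossless round-trip of
    stoichiometry, bounds and gene rules)."""
    path = Path(path)
    cols = [dialect.id, dialect.name, dialect.equation, dialect.lb, dialect.ub,
            dialect.genes, dialect.subsystem]
    with path.open("w", newline="") as fh:
        if model.name:
            fh.write(f"# model: {model.name}\n")
        if model.objective_id:
            fh.write(f"# objective: {model.objective_id}\n")
        if model.product_id:
            fh.write(f"# product: {model.product_id}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for rxn in model.reactions.values():
            writer.writerow(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn, model, dialect.default_compartment),
                    repr(rxn.lower_bound),
                    repr(rxn.upper_bound),
                    rxn.gene_rule,
                    rxn.subsystem,
                ]
            )


# ---------------------------------------------------------------------------
# screen result tables

RESULT_COLUMNS = [
    "perturbation_kind",
    "perturbation_spec",
    "status",
    "growth",
    "product_flux",
    "f_biomass",
    "f_product",
    "f_ph",
    "rank",
]


def write_results_tsv(results: Sequence, path: str | Path) -> None:
    """Write ranked screen results as TSV (columns: ``RESULT_COLUMNS``).

    Expects the results of one screen (one perturbation kind, already
    ranked); an empty sequence yields a header-only file.
    """
    kinds = {r.perturbation.kind for r in results}
    if len(kinds) > 1:
        raise ModelError(f"results mix perturbation kinds: {sorted(kinds)}")
    rows = [
        {
            "perturbation_kind": r.perturbation.kind,
            "perturbation_spec": r.perturbation.spec_string(),
            "status": r.status,
            "growth": r.growth,
            "product_flux": r.product_flux,
            "f_biomass": r.f_biomass,
            "f_product": r.f_product,
            "f_ph": r.f_ph,
            "rank": r.rank,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
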