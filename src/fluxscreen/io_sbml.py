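"""SBML model I/O via libsbml (Level 3 + fbc on write, L2/L3 on read).

Flux bounds travel in the fbc package when present; otherwise they fall
back to the reaction's reversibility flag with the conventional
``(−1000, 1000)`` / ``(0, 1000)`` defaults.  Gene rules are stored as
fbc gene-product associations.  The biomass objective is the active fbc
objective; the product reaction is stored as a second, inactive fbc
objective named ``product_rate`` so that model/product designation
round-trips without leaving the standard.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .gpr import Gpr, parse_gpr
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelError, Reaction

__all__ = ["load_sbml_model", "write_sbml_model", "SbmlError"]


class SbmlError(ModelError):
    """Unreadable or structurally unusable SBML."""


def _check(obj, what: str):
    if obj is None or (isinstance(obj, int) and obj != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise SbmlError(f"libsbml operation failed: {what}")
    return obj


# -- writing ----------------------------------------------------------------

def _association_from_node(node, fbc_rxn):
    """Build an Fbc association tree mirroring a parsed gene rule."""
    gpa = fbc_rxn.createGeneProductAssociation()

    def build(n, parent):
        if isinstance(n, str):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(f"G_{n}")
            return
        op, children = n
        assoc = parent.createAnd() if op == "and" else parent.createOr()
        for child in children:
            build(child, assoc)

    build(node, gpa)


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.name or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    for mid in {m.compartment for m in model.metabolites.values()}:
        comp = sbml_model.createCompartment()
        comp.setId(mid)
        comp.setConstant(True)

    for met in model.metabolites.values():
        if not libsbml.SyntaxChecker.isValidSBMLSId(met.id):
            raise SbmlError(f"metabolite id {met.id!r} is not a valid SBML SId")
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(met.charge)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(f"G_{gene}")
        gp.setLabel(gene)

    def bound_param(value: float, pid: str) -> str:
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        if not libsbml.SyntaxChecker.isValidSBMLSId(rxn.id):
            raise SbmlError(f"reaction id {rxn.id!r} is not a valid SBML SId")
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, f"{rxn.id}_lb"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, f"{rxn.id}_ub"))
        if rxn.gpr:
            _association_from_node(rxn.gpr.root, rplug)

    obj_list = mplug.createObjective() if model.objective_id else None
    if obj_list is not None:
        obj_list.setId("growth")
        obj_list.setType("maximize")
        fo = obj_list.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("growth")
    if model.product_id:
        pobj = mplug.createObjective()
        pobj.setId("product_rate")
        pobj.setType("maximize")
        fo = pobj.createFluxObjective()
        fo.setReaction(model.product_id)
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))


# -- reading ----------------------------------------------------------------

def _association_to_node(assoc):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return gid[2:] if gid.startswith("G_") else gid
    children = [_association_to_node(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
    op = "and" if assoc.isFbcAnd() else "or"
    return (op, children)


def _gpr_string(fbc_rxn) -> str:
    gpa = fbc_rxn.getGeneProductAssociation() if fbc_rxn else None
    if gpa is None:
        return ""
    node = _association_to_node(gpa.getAssociation())
    return Gpr(node).to_string() if node is not None else ""


def load_sbml_model(path: str | Path) -> MetabolicModel:
    """Read an SBML file (Level 2 or 3, fbc optional) into a model."""
    path = Path(path)
    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(f"{path.name}: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlError(f"{path.name}: no <model> element")
    mplug = sbml_model.getPlugin("fbc")

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gene_labels[gp.getId()] = label

    metabolites, boundary = [], set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        splug = sp.getPlugin("fbc")
        formula = charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )

    def resolve_bound(rplug, getter: str) -> float | None:
        if rplug is None:
            return None
        pid = getattr(rplug, getter)()
        if not pid:
            return None
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else None

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = resolve_bound(rplug, "getLowerFluxBound")
        ub = resolve_bound(rplug, "getUpperFluxBound")
        if lb is None or ub is None:
            if doc.getLevel() >= 3 and not sr.isSetReversible():
                raise SbmlError(
                    f"{path.name}: reaction {sr.getId()} has neither flux bounds "
                    "nor a reversibility flag"
                )
            reversible = sr.getReversible()
            lb = -DEFAULT_BOUND if (lb is None and reversible) else (lb or 0.0)
            ub = DEFAULT_BOUND if ub is None else ub
        gene_rule = _gpr_string(rplug)
        if gene_rule:
            # map gene-product ids back to labels where available
            gpr = parse_gpr(gene_rule)
            mapping = {g: gene_labels.get(f"G_{g}", gene_labels.get(g, g))
                       for g in gpr.genes}

            def rename(node):
                if isinstance(node, str):
                    return mapping[node]
                return (node[0], [rename(c) for c in node[1]])

            gene_rule = Gpr(rename(gpr.root)).to_string()
        reactions.append(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or sr.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=gene_rule,
                is_exchange=len(stoich) == 1,
            )
        )

    objective_id = product_id = None
    if mplug is not None:
        active = mplug.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getId() != (active.getId() if active else None) and \
                    obj.getNumFluxObjectives() > 0:
                product_id = obj.getFluxObjective(0).getReaction()
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        product_id=product_id,
        name=sbml_model.getId() or path.stem,
    )
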