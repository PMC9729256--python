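"""SBML Level 3 Version 1 + FBC v2 reading and writing.

Follows the community conventions used by deposited constraint-based
models: ``M_``/``R_``/``G_`` id prefixes, flux bounds as constant
parameters referenced through the FBC package, gene-reaction rules as FBC
gene-product associations, and the biomass objective as the active FBC
objective.  EC numbers travel in reaction notes (``EC Number: ...`` lines).
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .gpr import And, FALSE, Gene, GprRule, Or, parse_rule
from .model_core import Metabolite, Model, ModelValidationError, Reaction

__all__ = ["read_sbml_model", "write_sbml_model"]

_SBML_LEVEL, _SBML_VERSION, _FBC_VERSION = 3, 1, 2


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _clip(sid: str) -> str:
    # SBML SIds cannot contain most punctuation; ours are already clean
    return sid.replace("-", "__")


def _association_to_node(assoc):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc") \
            .getGeneProduct(assoc.getGeneProduct())
        label = gp.getLabel() if gp is not None and gp.getLabel() else \
            _strip("G_", assoc.getGeneProduct())
        return Gene(label)
    if assoc.isFbcAnd():
        children = tuple(
            _association_to_node(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return And(children)
    if assoc.isFbcOr():
        children = tuple(
            _association_to_node(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        return Or(children)
    raise ModelValidationError(f"unsupported GPR association element: {assoc}")


def _notes_text(sbase) -> str:
    if not sbase.isSetNotes():
        return ""
    text = libsbml.XMLNode.convertXMLNodeToString(sbase.getNotes())
    # crude tag strip is fine for our own plain <p> lines
    import re

    return re.sub(r"<[^>]+>", "\n", text)


def _ec_numbers_from_notes(text: str) -> set[str]:
    out = set()
    for line in text.splitlines():
        line = line.strip()
        if line.lower().startswith("ec number:"):
            for tok in line.split(":", 1)[1].replace(",", ";").split(";"):
                if tok.strip():
                    out.add(tok.strip())
    return out


def read_sbml_model(path: str | Path) -> Model:
    """Read an SBML L3 FBC model file into a :class:`Model`."""
    path = str(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"malformed SBML {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise ModelValidationError(f"malformed SBML {path}: no model element")
    fbc = smodel.getPlugin("fbc")

    model = Model(id=smodel.getId() or Path(path).stem)
    for i in range(smodel.getNumCompartments()):
        model.compartments.add(smodel.getCompartment(i).getId())

    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula() or None
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        model.add_metabolite(Metabolite(
            id=_strip("M_", sp.getId()),
            name=sp.getName() or "",
            formula=formula,
            charge=charge,
            compartment=sp.getCompartment(),
        ))

    def bound_value(pid: str, default: float) -> float:
        param = smodel.getParameter(pid) if pid else None
        return param.getValue() if param is not None else default

    for i in range(smodel.getNumReactions()):
        rx = smodel.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = bound_value(rfbc.getLowerFluxBound(), -1000.0)
            ub = bound_value(rfbc.getUpperFluxBound(), 1000.0)
        else:
            lb = -1000.0 if rx.getReversible() else 0.0
            ub = 1000.0
        gpr = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            node = _association_to_node(
                rfbc.getGeneProductAssociation().getAssociation()
            )
            if node is not None:
                gpr = GprRule(tree=node, source_text="")
        notes = _notes_text(rx)
        rid = _strip("R_", rx.getId())
        model.add_reaction(Reaction(
            id=rid,
            name=rx.getName() or "",
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            ec_numbers=_ec_numbers_from_notes(notes),
            is_exchange=(len(stoich) == 1),
            notes="",
        ))

    mnotes = _notes_text(smodel)
    for line in mnotes.splitlines():
        line = line.strip()
        if line.lower().startswith("balance exempt:"):
            model.balance_exempt = {
                t.strip() for t in line.split(":", 1)[1].split(",") if t.strip()
            }

    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            model.objective = _strip(
                "R_", active.getFluxObjective(0).getReaction()
            )
    if model.objective is None:
        raise ModelValidationError(
            f"{path}: no objective (active FBC objective with a flux "
            "objective is required)"
        )
    model.validate()
    return model


def _node_to_association(node, assoc, label_to_id: dict[str, str]) -> None:
    if isinstance(node, Gene):
        ref = assoc.createGeneProductRef()
        ref.setGeneProduct(label_to_id[node.name])
    elif isinstance(node, And):
        inner = assoc.createAnd()
        for child in node.children:
            _node_to_association(child, inner, label_to_id)
    elif isinstance(node, Or):
        inner = assoc.createOr()
        for child in node.children:
            _node_to_association(child, inner, label_to_id)
    elif node is FALSE or isinstance(node, type(FALSE)):
        raise ModelValidationError("cannot serialize a logically-false GPR")
    else:
        raise ModelValidationError(f"unknown GPR node {node!r}")


def write_sbml_model(model: Model, path: str | Path) -> None:
    """Write a :class:`Model` as SBML L3V1 with FBC v2."""
    ns = libsbml.SBMLNamespaces(_SBML_LEVEL, _SBML_VERSION, "fbc", _FBC_VERSION)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_clip(model.id))
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(True)
    if model.balance_exempt:
        smodel.setNotes(
            "<notes><body xmlns='http://www.w3.org/1999/xhtml'><p>"
            f"Balance exempt: {', '.join(sorted(model.balance_exempt))}"
            "</p></body></notes>"
        )

    for comp_id in sorted(model.compartments):
        comp = smodel.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = smodel.createSpecies()
        sp.setId(f"M_{_clip(met.id)}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        sfbc = sp.getPlugin("fbc")
        if met.formula is not None:
            sfbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sfbc.setCharge(int(met.charge))

    # flux-bound parameters, shared across equal values
    bound_param: dict[float, str] = {}

    def param_for(value: float) -> str:
        if value not in bound_param:
            pid = f"FB_{len(bound_param)}"
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    label_to_id = {
        gene: f"G_{_clip(gene)}" for gene in sorted(model.genes)
    }
    for gene, gid in label_to_id.items():
        gp = mplug.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(gene)

    for rxn in model.reactions.values():
        rx = smodel.createReaction()
        rx.setId(f"R_{_clip(rxn.id)}")
        rx.setName(rxn.name)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(f"M_{_clip(met_id)}")
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(param_for(rxn.lower_bound))
        rfbc.setUpperFluxBound(param_for(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _node_to_association(rxn.gpr.tree, gpa, label_to_id)
        if rxn.ec_numbers:
            rx.setNotes(
                "<notes><body xmlns='http://www.w3.org/1999/xhtml'><p>"
                f"EC Number: {'; '.join(sorted(rxn.ec_numbers))}"
                "</p></body></notes>"
            )

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{_clip(model.objective)}")
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelValidationError(f"could not write SBML to {path}")
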