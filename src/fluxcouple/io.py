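"""Model I/O: SBML Level 3 + fbc, and a two-sheet tabular dialect.

The tabular dialect is a directory (or basename prefix) holding
``reactions.tsv`` (id, equation, lower_bound, upper_bound, gpr, subsystem,
kind), ``metabolites.tsv`` (id, name, formula, charge, compartment) and an
optional ``model.tsv`` key/value sheet (biomass_reaction, maintenance_reaction,
gam, ngam). Equations use explicit metabolite ids with ``-->`` for
irreversible and ``<=>`` for reversible arrows, e.g.::

    glc_c + atp_c --> g6p_c + adp_c
    2 pyr_c <=> accoa_c
"""

from __future__ import annotations

import os
from typing import Dict, Optional, Tuple

import libsbml
import pandas as pd

from .gpr import GPR
from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    ReactionKind,
    infer_kind,
)


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed."""


def read_model(path: str, dialect: str = "sbml") -> MetabolicModel:
    """Read a model from ``path`` in the given dialect (``sbml``/``tabular``)."""
    if dialect == "sbml":
        return read_sbml(path)
    if dialect == "tabular":
        return read_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: str = "sbml") -> None:
    if dialect == "sbml":
        write_sbml(model, path)
    elif dialect == "tabular":
        write_tabular(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------- SBML ----

def read_sbml(path: str) -> MetabolicModel:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error in {path}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")

    metabolites = []
    compartments: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sfbc = sp.getPlugin("fbc")
        formula = sfbc.getChemicalFormula() if sfbc and sfbc.isSetChemicalFormula() else ""
        charge = sfbc.getCharge() if sfbc and sfbc.isSetCharge() else 0
        met = Metabolite(
            id=_unprefix(sp.getId(), "M_"),
            name=sp.getName() or "",
            formula=formula,
            charge=int(charge),
            compartment=sp.getCompartment() or "c",
        )
        metabolites.append(met)
        compartments[met.id] = met.compartment

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    objective_rxn = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rxn = _unprefix(obj.getFluxObjective(0).getReaction(), "R_")

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = _unprefix(rx.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _unprefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _unprefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound(), lb)
            if rfbc.isSetUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound(), ub)
        elif not rx.getReversible():
            lb = 0.0
        gpr = GPR(None)
        if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
            gpr = GPR(_association_to_node(
                rfbc.getGeneProductAssociation().getAssociation(), sbml_model
            ))
        kind = infer_kind(rid, stoich, compartments)
        if kind == ReactionKind.METABOLIC and rid == objective_rxn:
            kind = ReactionKind.BIOMASS
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                subsystem="",
                kind=kind,
                name=rx.getName() or "",
            )
        )

    biomass = next(
        (r.id for r in reactions if r.kind == ReactionKind.BIOMASS), objective_rxn
    )
    maintenance = next(
        (r.id for r in reactions if r.kind == ReactionKind.MAINTENANCE), None
    )
    model = MetabolicModel(
        id=sbml_model.getId() or os.path.basename(path),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass,
        maintenance_reaction_id=maintenance,
    )
    model.validate_gprs()
    return model


def _unprefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _association_to_node(assoc, sbml_model):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = sbml_model.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else assoc.getGeneProduct()
        return _unprefix(label, "G_")
    children = tuple(
        _association_to_node(assoc.getAssociation(i), sbml_model)
        for i in range(assoc.getNumAssociations())
    )
    if assoc.isFbcAnd():
        return ("and", children)
    if assoc.isFbcOr():
        return ("or", children)
    raise ModelParseError("unsupported gene association node")


def write_sbml(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(f"M_{met.id}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sfbc = sp.getPlugin("fbc")
        if met.formula:
            sfbc.setChemicalFormula(met.formula)
        sfbc.setCharge(int(met.charge))

    for gene in model.genes:
        gp = mfbc.createGeneProduct()
        gp.setId(f"G_{_sanitize(gene)}")
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(f"M_{met_id}")
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            gpa.setAssociation(_node_to_infix(r.gpr.root), True, False)

    obj = mfbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    mfbc.setActiveObjectiveId("obj")
    if model.biomass_reaction_id is not None:
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{model.biomass_reaction_id}")
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, path)


def _sanitize(gene: str) -> str:
    return "".join(c if c.isalnum() or c == "_" else "_" for c in gene)


def _node_to_infix(node) -> str:
    if isinstance(node, str):
        return f"G_{_sanitize(node)}"
    op, children = node
    return "(" + f" {op} ".join(_node_to_infix(c) for c in children) + ")"


# ------------------------------------------------------------- tabular ----

def _tabular_paths(path: str) -> Tuple[str, str, str]:
    if os.path.isdir(path):
        base = path
        return (
            os.path.join(base, "reactions.tsv"),
            os.path.join(base, "metabolites.tsv"),
            os.path.join(base, "model.tsv"),
        )
    return (f"{path}.reactions.tsv", f"{path}.metabolites.tsv", f"{path}.model.tsv")


def read_tabular(path: str) -> MetabolicModel:
    rxn_path, met_path, info_path = _tabular_paths(path)
    for p in (rxn_path, met_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    met_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxn_df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")

    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            formula=row.get("formula", ""),
            charge=int(row["charge"]) if str(row.get("charge", "")).strip() else 0,
            compartment=row.get("compartment", "c") or "c",
        )
        for _, row in met_df.iterrows()
    ]
    compartments = {m.id: m.compartment for m in metabolites}

    reactions = []
    for _, row in rxn_df.iterrows():
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ValueError as exc:
            raise ModelParseError(f"reaction {row['id']}: {exc}") from exc
        lb = float(row["lower_bound"]) if row.get("lower_bound", "") != "" else (
            -DEFAULT_BOUND if reversible else 0.0
        )
        ub = float(row["upper_bound"]) if row.get("upper_bound", "") != "" else DEFAULT_BOUND
        kind_cell = row.get("kind", "") or None
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=GPR.parse(row.get("gpr", "")),
                subsystem=row.get("subsystem", ""),
                kind=infer_kind(row["id"], stoich, compartments, kind_cell),
                name=row.get("name", ""),
            )
        )
    if rxn_df["id"].duplicated().any():
        dups = rxn_df["id"][rxn_df["id"].duplicated()].tolist()
        raise ModelParseError(f"duplicate reaction ids: {dups}")

    info: Dict[str, str] = {}
    if os.path.exists(info_path):
        info_df = pd.read_csv(info_path, sep="\t", dtype=str).fillna("")
        info = dict(zip(info_df["key"], info_df["value"]))

    biomass = info.get("biomass_reaction") or next(
        (r.id for r in reactions if r.kind == ReactionKind.BIOMASS), None
    )
    maintenance = info.get("maintenance_reaction") or next(
        (r.id for r in reactions if r.kind == ReactionKind.MAINTENANCE), None
    )
    model = MetabolicModel(
        id=info.get("id", os.path.basename(os.path.normpath(path))),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass,
        maintenance_reaction_id=maintenance,
        gam=float(info["gam"]) if info.get("gam") else None,
        ngam=float(info["ngam"]) if info.get("ngam") else None,
    )
    model.validate_gprs()
    return model


def write_tabular(model: MetabolicModel, path: str) -> None:
    rxn_path, met_path, info_path = _tabular_paths(path)
    if os.path.isdir(path) or not os.path.splitext(path)[1]:
        os.makedirs(path, exist_ok=True)
        rxn_path, met_path, info_path = _tabular_paths(path)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ]
    ).to_csv(met_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.reversible),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "kind": r.kind.value,
            }
            for r in model.reactions
        ]
    ).to_csv(rxn_path, sep="\t", index=False)
    info = {
        "id": model.id,
        "biomass_reaction": model.biomass_reaction_id or "",
        "maintenance_reaction": model.maintenance_reaction_id or "",
        "gam": "" if model.gam is None else model.gam,
        "ngam": "" if model.ngam is None else model.ngam,
    }
    pd.DataFrame({"key": list(info), "value": list(info.values())}).to_csv(
        info_path, sep="\t", index=False
    )


def parse_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``2 a_c + b_c --> c_c`` / ``... <=> ...`` into stoichiometry."""
    if "<=>" in text:
        lhs, rhs = text.split("<=>")
        reversible = True
    elif "-->" in text:
        lhs, rhs = text.split("-->")
        reversible = False
    elif "<--" in text:
        rhs, lhs = text.split("<--")
        reversible = False
    else:
        raise ValueError(f"no reaction arrow in {text!r}")
    stoich: Dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ValueError(f"bad term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    return stoich, reversible


def format_equation(stoich: Dict[str, float], reversible: bool) -> str:
    def side(items):
        return " + ".join(
            met if abs(c) == 1 else f"{abs(c):g} {met}" for met, c in items
        )

    lhs = [(m, c) for m, c in stoich.items() if c < 0]
    rhs = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "-->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()
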