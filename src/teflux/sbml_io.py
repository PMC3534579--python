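"""SBML reading and writing for :class:`~teflux.model.MetabolicModel`.

Models are written as SBML L3V1 with the fbc-v2 extension (flux bounds as
parameters, GPRs as ``geneProductAssociation``).  The reader additionally
accepts the older COBRA dialects found in the wild: kinetic-law
``LOWER_BOUND``/``UPPER_BOUND`` parameters, ``GENE_ASSOCIATION:`` notes, and
boundary species marked either by ``boundaryCondition="true"`` or by the
compartment-suffix convention (a compartment literally named ``b``, as the
first human reconstruction uses for its ``_b`` species).
"""

from __future__ import annotations

import logging
import re

import libsbml

from .gpr import parse_gpr
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

log = logging.getLogger(__name__)

__all__ = [
    "SBMLReadError",
    "load_sbml",
    "write_sbml",
    "add_production_objective",
    "production_reaction_id",
]

BOUNDARY_COMPARTMENT = "b"

_GENE_ASSOC_RE = re.compile(r"GENE[_ ]?ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE)


class SBMLReadError(ValueError):
    pass


def _sanitize(token: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", token)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _association_to_infix(assoc) -> str:
    """Recursively render an fbc association tree as an and/or infix rule."""
    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        if gp is not None and gp.isSetLabel() and gp.getLabel():
            return gp.getLabel()
        return _strip_prefix(assoc.getGeneProduct(), "G_")
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_association_to_infix(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_association_to_infix(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    raise SBMLReadError(f"unsupported fbc association node: {type(assoc).__name__}")


def _notes_gene_association(sbase) -> str | None:
    if not sbase.isSetNotes():
        return None
    m = _GENE_ASSOC_RE.search(sbase.getNotesString())
    if m is None:
        return None
    return m.group(1).strip()


def _reaction_bounds(rxn, sbml_model) -> tuple[float, float] | None:
    fbc = rxn.getPlugin("fbc")
    if fbc is not None and fbc.isSetLowerFluxBound() and fbc.isSetUpperFluxBound():
        lo = sbml_model.getParameter(fbc.getLowerFluxBound())
        hi = sbml_model.getParameter(fbc.getUpperFluxBound())
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    if rxn.isSetKineticLaw():
        kl = rxn.getKineticLaw()
        lo = kl.getParameter("LOWER_BOUND")
        hi = kl.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    return None


def load_sbml(
    path: str,
    boundary_compartment: str = BOUNDARY_COMPARTMENT,
) -> MetabolicModel:
    """Read an SBML (L2 or L3, fbc optional) file into a MetabolicModel.

    Species are boundary when ``boundaryCondition`` is set or their
    compartment equals *boundary_compartment*.  Reactions without declared
    bounds default to [-1000, 1000] if reversible, [0, 1000] otherwise (with
    a warning).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    errors = [doc.getError(i) for i in range(doc.getNumErrors())]
    fatal = [e for e in errors if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
    if fatal:
        lines = "; ".join(f"line {e.getLine()}: {e.getMessage()}" for e in fatal[:5])
        raise SBMLReadError(f"SBML parse error in {path}: {lines}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError(f"{path}: no <model> element")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        comp = sp.getCompartment() or "c"
        metabolites.append(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=comp,
                is_boundary=bool(sp.getBoundaryCondition())
                or comp == boundary_compartment,
            )
        )
    met_ids = {m.id for m in metabolites}

    reactions = []
    defaulted = []
    for rxn in sbml_model.getListOfReactions():
        rid = _strip_prefix(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for ref, sign in [(r, -1.0) for r in rxn.getListOfReactants()] + [
            (p, +1.0) for p in rxn.getListOfProducts()
        ]:
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + sign * ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        missing = set(stoich) - met_ids
        if missing:
            raise SBMLReadError(
                f"reaction {rid!r} references undeclared species: {sorted(missing)}"
            )

        bounds = _reaction_bounds(rxn, sbml_model)
        if bounds is None:
            reversible = rxn.getReversible()
            bounds = (-DEFAULT_BOUND if reversible else 0.0, DEFAULT_BOUND)
            defaulted.append(rid)

        rule = None
        fbc = rxn.getPlugin("fbc")
        if fbc is not None and fbc.isSetGeneProductAssociation():
            rule = _association_to_infix(fbc.getGeneProductAssociation().getAssociation())
        if rule is None:
            rule = _notes_gene_association(rxn) or ""

        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=bounds[0],
                upper_bound=bounds[1],
                gpr=parse_gpr(rule),
                name=rxn.getName() or "",
            )
        )

    if defaulted:
        log.warning(
            "%d reactions without declared flux bounds; defaulted to ±%g: %s%s",
            len(defaulted), DEFAULT_BOUND, ", ".join(defaulted[:5]),
            "..." if len(defaulted) > 5 else "",
        )
    model = MetabolicModel(metabolites, reactions,
                           model_id=sbml_model.getId() or "model")
    s = model.stats()
    log.info(
        "loaded %s: %d metabolites (%d internal), %d reactions, %d genes",
        path, s["metabolites"], s["non_boundary_metabolites"],
        s["reactions"], s["genes"],
    )
    return model


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML L3V1 + fbc v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + _sanitize(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setBoundaryCondition(met.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    gene_param = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _sanitize(gene))
        gp.setLabel(gene)
        gene_param[gene] = "G_" + _sanitize(gene)

    def bound_param(value: float) -> str:
        pid = "fb_" + _sanitize(repr(value))
        if sm.getParameter(pid) is None:
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId("R_" + _sanitize(rxn.id))
        r.setName(rxn.name)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies("M_" + _sanitize(mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            infix = rxn.gpr.to_string()
            for gene, gid in gene_param.items():
                infix = re.sub(rf"(?<![\w]){re.escape(gene)}(?![\w])", gid, infix)
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(infix, True, False)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


# ---------------------------------------------------------------------------
# production objectives
# ---------------------------------------------------------------------------

def production_reaction_id(met_id: str) -> str:
    return f"DM_{met_id}"


def _find_export_reaction(model: MetabolicModel, met_id: str) -> str | None:
    for r in model.reactions:
        if (
            r.stoichiometry == {met_id: -1.0}
            and r.lower_bound >= 0
            and r.upper_bound >= DEFAULT_BOUND
        ):
            # a genuine unit-export with ample capacity: its flux IS the
            # production rate
            return r.id
    return None


def add_production_objective(
    model: MetabolicModel, met_id: str
) -> tuple[MetabolicModel, str]:
    """Return ``(model', reaction_id)`` where *reaction_id* exports one unit
    of *met_id* with bounds [0, 1000].

    An existing irreversible single-metabolite export is reused (the input
    model is then returned unchanged); otherwise a demand reaction is added.
    The input model is never modified.  Boundary metabolites are rejected:
    they sit outside the steady-state constraint and their "production" is
    not defined by the network.
    """
    met = model.metabolite(met_id)
    if met.is_boundary:
        raise ValueError(
            f"{met_id!r} is a boundary metabolite; production objectives are "
            "defined only for internal (steady-state) species"
        )
    existing = _find_export_reaction(model, met_id)
    if existing is not None:
        return model, existing
    rid = production_reaction_id(met_id)
    if model.has_reaction(rid):  # id collision without export semantics
        rid = rid + "_obj"
    demand = Reaction(rid, {met_id: -1.0}, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
    return model.with_reactions(model.reactions + [demand]), rid
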