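"""SBML import/export and model statistics.

Models are written as SBML Level 3 Version 1 with the flux-balance
("fbc" v2) package carrying the flux bounds as global parameters.  Gene
associations are stored as a ``GENE_ASSOCIATION:`` line in the reaction
notes (the classic COBRA convention — kept canonical here because
annotation-era models stored them exactly this way), alongside ``KIND``,
``EVIDENCE`` and ``SUBSYSTEM`` note lines.  Reading accepts both these
documents and foreign Level 2/3 files: unknown notes are tolerated and
missing bounds fall back to reversibility-derived defaults.

Serialization is canonical (components written in sorted-id order), so
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import libsbml

from .core import (
    COMPARTMENT_SUFFIX,
    DEFAULT_BOUND,
    SUFFIX_COMPARTMENT,
    CompartmentalizedModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    gpr_genes,
)

__all__ = ["write_sbml", "read_sbml", "model_statistics", "ModelStatistics",
           "SBMLError", "sanitize_sid"]


class SBMLError(ValueError):
    """Problems reading or writing SBML documents."""


_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_sid(raw: str) -> str:
    """Deterministically map an id onto a valid SBML SId."""
    if _SID_OK.match(raw):
        return raw
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not out or not re.match(r"[A-Za-z_]", out[0]):
        out = "_" + out
    return out


_COMPARTMENT_ORDER = ["cytosol", "plastid", "mitochondrion", "microbody",
                      "extracellular"]


def _notes_block(lines: List[Tuple[str, str]]) -> str:
    body = "".join(
        f'    <p>{key}: {value}</p>\n' for key, value in lines if value != ""
    )
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">\n' + body + "  </body>"
    )


_NOTE_LINE = re.compile(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", re.DOTALL)


def _parse_notes(notes: Optional[str]) -> Dict[str, str]:
    if not notes:
        return {}
    return {m.group(1): m.group(2) for m in _NOTE_LINE.finditer(notes)}


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_sbml(model: CompartmentalizedModel, path: Optional[Union[str, Path]] = None) -> str:
    """Serialize a model to SBML L3V1(+fbc); returns the document string.

    Ids not expressible as SBML SIds are sanitized deterministically; the
    mapping is recorded in the model-level notes.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(sanitize_sid(model.id))
    if model.name:
        sbml_model.setName(model.name)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    id_map: Dict[str, str] = {}

    def sid(raw: str) -> str:
        clean = sanitize_sid(raw)
        if clean != raw:
            id_map[raw] = clean
        return clean

    model_notes: List[Tuple[str, str]] = []
    if model.biomass_reaction:
        model_notes.append(("BIOMASS_REACTION", model.biomass_reaction))
    if model.biomass_components:
        model_notes.append(("BIOMASS_COMPONENTS", ",".join(model.biomass_components)))
    used_compartments = sorted(
        {m.compartment for m in model.metabolites.values()},
        key=_COMPARTMENT_ORDER.index,
    )
    for comp in used_compartments:
        c = sbml_model.createCompartment()
        c.setId(COMPARTMENT_SUFFIX[comp])
        c.setName(comp)
        c.setConstant(True)
        c.setSize(1.0)
        c.setSpatialDimensions(3)

    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        s = sbml_model.createSpecies()
        s.setId(sid(f"M_{mid}"))
        s.setName(met.name or mid)
        s.setCompartment(COMPARTMENT_SUFFIX[met.compartment])
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        s.setInitialConcentration(0.0)
        splug = s.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        notes = []
        if met.formula == "":
            notes.append(("MASSLESS", "true"))  # e.g. the photon
        if met.is_boundary:
            notes.append(("BOUNDARY", "true"))
        if notes:
            s.setNotes(_notes_block(notes))

    # bounds as global fbc parameters (shared where values coincide)
    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value in bound_params:
            return bound_params[value]
        pid = f"fb_{len(bound_params)}"
        p = sbml_model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        bound_params[value] = pid
        return pid

    # pre-create parameters in a deterministic order
    values = sorted(
        {model.reactions[r].lower_bound for r in model.reaction_ids}
        | {model.reactions[r].upper_bound for r in model.reaction_ids}
    )
    for v in values:
        bound_param(v)

    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        r = sbml_model.createReaction()
        r.setId(sid(f"R_{rid}"))
        r.setName(rxn.name or rid)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = r.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = r.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(sanitize_sid(f"M_{mid}"))
            ref.setConstant(True)
        notes = []
        if rxn.gene_association:
            notes.append(("GENE_ASSOCIATION", rxn.gene_association))
        notes.append(("KIND", rxn.kind))
        notes.append(("EVIDENCE", rxn.compartment_evidence))
        if rxn.subsystem:
            notes.append(("SUBSYSTEM", rxn.subsystem))
        r.setNotes(_notes_block(notes))

    if id_map:
        model_notes.append(("ID_MAP", json.dumps(id_map, sort_keys=True)))
    if model_notes:
        sbml_model.setNotes(_notes_block(model_notes))

    text = libsbml.writeSBMLToString(doc)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(source: Union[str, Path]) -> CompartmentalizedModel:
    """Parse an SBML document (path or document string) into a model.

    Inverse of :func:`write_sbml` on documents it produced; foreign L2/L3
    documents are read tolerantly (missing bounds become reversibility-
    derived defaults, unknown compartments raise a structural error).
    """
    text: str
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("<")
    ):
        p = Path(source)
        if not p.exists():
            raise SBMLError(f"no such SBML file: {source}")
        text = p.read_text()
    else:
        text = str(source)
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        line = err.getLine() if err is not None else "?"
        msg = err.getMessage() if err is not None else "unknown parse error"
        raise SBMLError(f"SBML parse error at line {line}: {msg}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError("document contains no model")

    compartment_names: Dict[str, str] = {}
    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        label = c.getName() or c.getId()
        cid = c.getId()
        if label in SUFFIX_COMPARTMENT.values() or label in SUFFIX_COMPARTMENT:
            compartment_names[cid] = (
                SUFFIX_COMPARTMENT.get(label, label)
            )
        elif cid in SUFFIX_COMPARTMENT:
            compartment_names[cid] = SUFFIX_COMPARTMENT[cid]
        else:
            raise SBMLError(f"species compartment {cid!r} is not recognised")

    model_notes = _parse_notes(sbml_model.getNotesString() if sbml_model.isSetNotes() else None)

    model = CompartmentalizedModel(
        id=sbml_model.getId() or "model",
        name=sbml_model.getName() or "",
    )
    species_map: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        mid = _strip_prefix(s.getId(), "M_")
        comp = compartment_names[s.getCompartment()]
        notes = _parse_notes(s.getNotesString() if s.isSetNotes() else None)
        formula = None
        splug = s.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        if notes.get("MASSLESS") == "true":
            formula = ""
        model.add_metabolite(
            Metabolite(
                id=mid,
                compartment=comp,
                name=s.getName() or mid,
                formula=formula,
                is_boundary=notes.get("BOUNDARY") == "true"
                or comp == "extracellular",
            )
        )
        species_map[s.getId()] = mid

    params: Dict[str, float] = {}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        params[p.getId()] = p.getValue()

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        rid = _strip_prefix(r.getId(), "R_")
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = species_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = species_map[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        reversible = r.getReversible()
        lb = -DEFAULT_BOUND if reversible else 0.0
        ub = DEFAULT_BOUND
        rplug = r.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound() and rplug.getLowerFluxBound() in params:
                lb = params[rplug.getLowerFluxBound()]
            if rplug.isSetUpperFluxBound() and rplug.getUpperFluxBound() in params:
                ub = params[rplug.getUpperFluxBound()]
        else:  # L2: kinetic-law parameters, if present
            kl = r.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND":
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND":
                        ub = p.getValue()
        notes = _parse_notes(r.getNotesString() if r.isSetNotes() else None)
        model.add_reaction(
            Reaction(
                id=rid,
                name=r.getName() or rid,
                stoichiometry=stoich,
                reversible=reversible or lb < 0,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=notes.get("GENE_ASSOCIATION", ""),
                kind=notes.get("KIND", _infer_kind(model, stoich)),
                compartment_evidence=notes.get("EVIDENCE", "not_applicable"),
                subsystem=notes.get("SUBSYSTEM", ""),
            )
        )

    if "BIOMASS_REACTION" in model_notes:
        model.biomass_reaction = model_notes["BIOMASS_REACTION"]
    if "BIOMASS_COMPONENTS" in model_notes:
        model.biomass_components = model_notes["BIOMASS_COMPONENTS"].split(",")
    return model


def _infer_kind(model: CompartmentalizedModel, stoich: Dict[str, float]) -> str:
    comps = {model.metabolites[m].compartment for m in stoich}
    if len(stoich) == 1 and comps == {"extracellular"}:
        return "exchange"
    if len(comps) == 2:
        return "transport"
    return "enzymatic"


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelStatistics:
    """Reconstruction-characteristics counts."""

    gene_reaction_associations: int
    unique_reactions: int
    unique_orfs: int
    metabolites: int
    compartments: int
    biomass_drains: int
    intercellular_transporters: int
    interorganelle_transporters: int
    gap_reactions: int

    def to_dict(self) -> Dict[str, int]:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def table(self) -> str:
        rows = [
            ("Gene-reaction-association entries", self.gene_reaction_associations),
            ("Unique metabolic reactions", self.unique_reactions),
            ("Unique ORFs", self.unique_orfs),
            ("Metabolites", self.metabolites),
            ("Cellular compartments", self.compartments),
            ("Biomass drains", self.biomass_drains),
            ("Intercellular transporters", self.intercellular_transporters),
            ("Inter-organelle transporters", self.interorganelle_transporters),
            ("Gaps (non-enzymatic reactions)", self.gap_reactions),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def model_statistics(
    model: CompartmentalizedModel, distinct_stoichiometry: bool = False
) -> ModelStatistics:
    """Count the reconstruction characteristics of a model.

    ``unique_reactions`` counts distinct reaction ids by default, so
    compartmental copies of one biochemical transformation are distinct;
    with ``distinct_stoichiometry=True`` reactions are collapsed by their
    canonical stoichiometry instead.  Counts are order-invariant.
    """
    genes = set()
    gra = 0
    inter_cell = 0
    inter_org = 0
    gaps = 0
    drains = 0
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        g = gpr_genes(rxn.gene_association)
        genes.update(g)
        gra += len(g)
        if rxn.kind == "transport":
            comps = model.reaction_compartments(rxn)
            if "extracellular" in comps:
                inter_cell += 1
            else:
                inter_org += 1
        elif rxn.kind == "non_enzymatic_gap":
            gaps += 1
        elif rxn.kind == "biomass_drain":
            if rid != model.biomass_reaction:
                drains += 1
    if distinct_stoichiometry:
        unique = len(
            {model.reactions[r].canonical_stoichiometry() for r in model.reaction_ids}
        )
    else:
        unique = len(model.reactions)
    cellular = {
        m.compartment for m in model.metabolites.values()
    } - {"extracellular"}
    return ModelStatistics(
        gene_reaction_associations=gra,
        unique_reactions=unique,
        unique_orfs=len(genes),
        metabolites=len(model.metabolites),
        compartments=len(cellular),
        biomass_drains=drains,
        intercellular_transporters=inter_cell,
        interorganelle_transporters=inter_org,
        gap_reactions=gaps,
    )
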