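"""Curation pipeline: raw gene-centric reaction tables to a simulation-ready model.

The pipeline stages mirror the manual curation steps used when deriving a
compartmentalized network from a pathway-database dump:

1. :func:`merge_duplicate_compounds` — collapse synonymous compound labels
   (e.g. non-specific vs. stereospecific sugar names) and the duplicate
   reactions that result.
2. :func:`expand_polymer_reactions` — rewrite degenerate polymer-elongation
   reactions (``polymer(n) + monomer -> polymer(n+1)``) in terms of monomer
   units, and reject generic "R"-group species.
3. :func:`assign_compartments` — place each reaction using localization
   evidence with precedence literature > homolog > cytosol-by-default;
   multiple literature claims duplicate the reaction, one copy per
   compartment.
4. :func:`add_transporters` / :func:`add_exchanges` — append manually curated
   transport and boundary reactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import (
    COMPARTMENT_SUFFIX,
    COMPARTMENTS,
    CompartmentalizedModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_formula,
)

__all__ = [
    "EvidenceRecord",
    "SynonymTable",
    "TransporterEntry",
    "CurationError",
    "merge_duplicate_compounds",
    "expand_polymer_reactions",
    "assign_compartments",
    "add_transporters",
    "add_exchanges",
    "read_reaction_table",
    "write_reaction_table",
    "read_evidence_table",
    "read_transporter_table",
]


class CurationError(ValueError):
    """A configuration or data problem detected during curation."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One localization claim for a reaction or enzyme."""

    target_id: str
    compartment: str
    source: str  # "literature" or "homolog"
    citation: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("literature", "homolog"):
            raise CurationError(f"evidence source must be literature/homolog, got {self.source!r}")
        if self.compartment not in COMPARTMENTS:
            raise CurationError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class TransporterEntry:
    """One manually curated transporter: species moved between two compartments.

    ``cotransport`` optionally names a species antiported in the opposite
    direction (e.g. the phosphate counter-substrate of plastid translocators,
    or ADP for adenylate carriers).
    """

    species: str
    compartment_a: str
    compartment_b: str
    reversible: bool = True
    cotransport: str = ""

    def __post_init__(self) -> None:
        for comp in (self.compartment_a, self.compartment_b):
            if comp not in COMPARTMENTS:
                raise CurationError(f"unknown compartment {comp!r}")
        if self.compartment_a == self.compartment_b:
            raise CurationError("transporter compartments must differ")


class SynonymTable:
    """Mapping from non-canonical compound ids to canonical ones.

    The mapping must be acyclic; chains are resolved to their terminal
    canonical id so that one application is idempotent.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._resolved: Dict[str, str] = {}
        for key in mapping:
            seen = [key]
            cur = key
            while cur in mapping:
                cur = mapping[cur]
                if cur in seen:
                    raise CurationError(f"synonym cycle involving {cur!r}")
                seen.append(cur)
            self._resolved[key] = cur

    def resolve(self, compound_id: str) -> str:
        return self._resolved.get(compound_id, compound_id)

    def __len__(self) -> int:
        return len(self._resolved)


def _or_join(gprs: Sequence[str]) -> str:
    """OR-combine gene associations, the conservative union of catalysts."""
    seen: List[str] = []
    for g in gprs:
        g = g.strip()
        if g and g not in seen:
            seen.append(g)
    if not seen:
        return ""
    if len(seen) == 1:
        return seen[0]
    return " or ".join(f"({g})" if (" and " in g or " or " in g) else g for g in seen)


def merge_duplicate_compounds(
    model: CompartmentalizedModel, synonyms: SynonymTable
) -> Tuple[CompartmentalizedModel, Dict[str, List]]:
    """Rewrite all references to canonical compound ids and collapse duplicates.

    Reactions whose stoichiometry becomes identical to another's are merged,
    their gene associations OR-combined.  Returns the new model and a report
    with keys ``species_merged`` and ``reactions_merged``.
    """
    report: Dict[str, List] = {"species_merged": [], "reactions_merged": []}
    new = CompartmentalizedModel(id=model.id, name=model.name)
    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        canon = synonyms.resolve(mid)
        if canon != mid:
            report["species_merged"].append((mid, canon))
        if canon not in new.metabolites:
            new.add_metabolite(met if canon == mid else replace(met, id=canon))
    seen_stoich: Dict[tuple, str] = {}
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        stoich: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            canon = synonyms.resolve(mid)
            stoich[canon] = stoich.get(canon, 0.0) + coeff
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rxn = replace(rxn, stoichiometry=stoich)
        key = rxn.canonical_stoichiometry()
        if key in seen_stoich:
            keep_id = seen_stoich[key]
            keep = new.reactions[keep_id]
            new.reactions[keep_id] = replace(
                keep,
                gene_association=_or_join([keep.gene_association, rxn.gene_association]),
            )
            report["reactions_merged"].append((keep_id, rid))
        else:
            seen_stoich[key] = rxn.id
            new.add_reaction(rxn)
    new.biomass_components = [c for c in model.biomass_components if c in new.reactions]
    new.biomass_reaction = model.biomass_reaction
    return new, report


_POLYMER_INDEX = re.compile(r"^(?P<base>.+?)\(n(?:\+(?P<off>\d+))?\)(?:_[a-z])?$")


def _polymer_base(mid: str) -> Optional[str]:
    m = _POLYMER_INDEX.match(mid)
    return m.group("base") if m else None


def _polymer_offset(mid: str) -> int:
    m = _POLYMER_INDEX.match(mid)
    return int(m.group("off") or 0) if m else 0


def _has_r_group(met: Metabolite) -> bool:
    if met.formula:
        if "R" in parse_formula(met.formula) or "X" in parse_formula(met.formula):
            return True
    return False


def expand_polymer_reactions(
    model: CompartmentalizedModel, monomer_map: Mapping[str, str]
) -> CompartmentalizedModel:
    """Rewrite degenerate polymer-elongation reactions in monomer form.

    A reaction of the form ``P(n) + X -> P(n+1)`` becomes ``X -> monomer(P)``
    (a monomer-accumulation drain); the shrinking form becomes a monomer
    release.  Species carrying generic "R"/"X" groups are rejected.
    """
    new = CompartmentalizedModel(id=model.id, name=model.name)
    polymer_ids = {
        mid: base
        for mid in model.metabolite_ids
        if (base := _polymer_base(mid)) is not None
    }
    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        if mid in polymer_ids:
            continue  # indexed polymer species are eliminated
        new.add_metabolite(met)
    # ensure monomer species exist
    for base in sorted(set(polymer_ids.values())):
        if base not in monomer_map:
            raise CurationError(f"polymer {base!r} has no monomer mapping")
        monomer = monomer_map[base]
        if monomer not in new.metabolites:
            template = next(
                model.metabolites[mid]
                for mid, b in sorted(polymer_ids.items())
                if b == base
            )
            new.add_metabolite(
                Metabolite(id=monomer, compartment=template.compartment,
                           name=f"{base} monomer unit")
            )
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        offenders = [
            mid for mid in rxn.stoichiometry if _has_r_group(model.metabolites[mid])
        ]
        if offenders:
            raise CurationError(
                f"reaction {rid!r} uses generic R-group species {offenders}"
            )
        stoich: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            if mid in polymer_ids:
                monomer = monomer_map[polymer_ids[mid]]
                # the net change in stored units is the index-weighted sum:
                # P(n) -> P(n+1) accumulates one monomer unit (product side),
                # P(n+1) -> P(n) releases one from storage (reactant side)
                stoich[monomer] = stoich.get(monomer, 0.0) + coeff * _polymer_offset(mid)
            else:
                stoich[mid] = stoich.get(mid, 0.0) + coeff
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        new.add_reaction(replace(rxn, stoichiometry=stoich))
    new.biomass_components = list(model.biomass_components)
    new.biomass_reaction = model.biomass_reaction
    return new


def assign_compartments(
    reactions: Iterable[Reaction],
    evidence: Iterable[EvidenceRecord],
    default: str = "cytosol",
) -> List[Reaction]:
    """Compartmentalize raw (suffix-free) reactions using localization evidence.

    Precedence is literature > homolog > cytosol-by-default.  Several
    literature claims for one reaction produce one compartmental copy per
    claimed compartment (a reaction may genuinely occur in more than one
    compartment, e.g. plastidic and cytosolic glycolysis).  Metabolite ids
    gain the compartment suffix; reaction ids gain it when more than zero
    copies are made (always, for determinism).
    """
    by_target: Dict[str, List[EvidenceRecord]] = {}
    for rec in evidence:
        by_target.setdefault(rec.target_id, []).append(rec)
    out: List[Reaction] = []
    for rxn in reactions:
        recs = by_target.get(rxn.id, [])
        lit = sorted({r.compartment for r in recs if r.source == "literature"})
        hom = sorted({r.compartment for r in recs if r.source == "homolog"})
        if lit:
            placements = [(c, "literature") for c in lit]
        elif hom:
            placements = [(hom[0], "homolog")]
        else:
            placements = [(default, "default_cytosol")]
        for comp, source in placements:
            suffix = COMPARTMENT_SUFFIX[comp]
            stoich = {
                f"{mid}_{suffix}": coeff for mid, coeff in rxn.stoichiometry.items()
            }
            out.append(
                replace(
                    rxn,
                    id=f"{rxn.id}_{suffix}",
                    stoichiometry=stoich,
                    compartment_evidence=source,
                )
            )
    return out


def _ensure_species(
    model: CompartmentalizedModel,
    species: str,
    compartment: str,
    formula_table: Optional[Mapping[str, Optional[str]]] = None,
    names: Optional[Mapping[str, str]] = None,
    create_missing: bool = True,
) -> str:
    suffix = COMPARTMENT_SUFFIX[compartment]
    mid = f"{species}_{suffix}"
    if mid not in model.metabolites:
        if not create_missing:
            raise CurationError(
                f"species {species!r} absent from compartment {compartment!r}"
            )
        model.add_metabolite(
            Metabolite(
                id=mid,
                compartment=compartment,
                name=(names or {}).get(species, species),
                formula=(formula_table or {}).get(species),
                is_boundary=compartment == "extracellular",
            )
        )
    return mid


def add_transporters(
    model: CompartmentalizedModel,
    entries: Iterable[TransporterEntry],
    formula_table: Optional[Mapping[str, Optional[str]]] = None,
    names: Optional[Mapping[str, str]] = None,
    create_missing: bool = True,
) -> Tuple[CompartmentalizedModel, Dict[str, int]]:
    """Append manually curated transport reactions.

    Returns the new model and counts split into ``intercellular``
    (touching the extracellular space) and ``interorganelle`` transporters.
    """
    new = model.copy()
    counts = {"intercellular": 0, "interorganelle": 0}
    for entry in entries:
        sa = COMPARTMENT_SUFFIX[entry.compartment_a]
        sb = COMPARTMENT_SUFFIX[entry.compartment_b]
        mid_a = _ensure_species(new, entry.species, entry.compartment_a,
                                formula_table, names, create_missing)
        mid_b = _ensure_species(new, entry.species, entry.compartment_b,
                                formula_table, names, create_missing)
        stoich: Dict[str, float] = {mid_a: -1.0, mid_b: 1.0}
        if entry.cotransport:
            co_a = _ensure_species(new, entry.cotransport, entry.compartment_a,
                                   formula_table, names, create_missing)
            co_b = _ensure_species(new, entry.cotransport, entry.compartment_b,
                                   formula_table, names, create_missing)
            stoich[co_b] = stoich.get(co_b, 0.0) - 1.0
            stoich[co_a] = stoich.get(co_a, 0.0) + 1.0
        rxn = Reaction(
            id=f"T_{entry.species}_{sa}{sb}",
            name=f"{entry.species} transport {entry.compartment_a}<->{entry.compartment_b}"
            if entry.reversible
            else f"{entry.species} transport {entry.compartment_a}->{entry.compartment_b}",
            stoichiometry=stoich,
            reversible=entry.reversible,
            kind="transport",
            compartment_evidence="literature",
            subsystem="transport",
        )
        if rxn.id in new.reactions:
            continue  # idempotent: already added
        new.add_reaction(rxn)
        if "extracellular" in (entry.compartment_a, entry.compartment_b):
            counts["intercellular"] += 1
        else:
            counts["interorganelle"] += 1
    return new, counts


def add_exchanges(
    model: CompartmentalizedModel,
    species_bounds: Mapping[str, Tuple[float, float]],
    formula_table: Optional[Mapping[str, Optional[str]]] = None,
    names: Optional[Mapping[str, str]] = None,
) -> CompartmentalizedModel:
    """Append boundary exchange reactions for extracellular species.

    Flux convention: positive = secretion, negative = uptake; the lower bound
    therefore limits uptake.
    """
    new = model.copy()
    for species, (lb, ub) in sorted(species_bounds.items()):
        mid = _ensure_species(new, species, "extracellular", formula_table, names)
        rid = f"EX_{species}_e"
        if rid in new.reactions:
            continue
        new.add_reaction(
            Reaction(
                id=rid,
                name=f"{species} exchange",
                stoichiometry={mid: -1.0},
                reversible=lb < 0,
                lower_bound=lb,
                upper_bound=ub,
                kind="exchange",
                compartment_evidence="not_applicable",
                subsystem="exchange",
            )
        )
    return new


# ---------------------------------------------------------------------------
# tab-delimited interchange
# ---------------------------------------------------------------------------


def write_reaction_table(model: CompartmentalizedModel, path: Path) -> None:
    from .core import format_reaction_equation

    rows = []
    for rid in model.reaction_ids:
        r = model.reactions[rid]
        rows.append(
            {
                "reaction_id": rid,
                "name": r.name,
                "equation": format_reaction_equation(r.stoichiometry, r.reversible),
                "gene_association": r.gene_association,
                "kind": r.kind,
                "evidence": r.compartment_evidence,
                "subsystem": r.subsystem,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reaction_table(path: Path) -> List[Reaction]:
    from .core import parse_reaction_equation

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    reactions = []
    for _, row in df.iterrows():
        stoich, reversible = parse_reaction_equation(row["equation"])
        reactions.append(
            Reaction(
                id=row["reaction_id"],
                name=row.get("name", ""),
                stoichiometry=stoich,
                reversible=reversible,
                gene_association=row.get("gene_association", ""),
                kind=row.get("kind", "enzymatic") or "enzymatic",
                compartment_evidence=row.get("evidence", "not_applicable")
                or "not_applicable",
                subsystem=row.get("subsystem", ""),
            )
        )
    return reactions


def read_evidence_table(path: Path) -> List[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        EvidenceRecord(
            target_id=row["enzyme_or_reaction_id"],
            compartment=row["compartment"],
            source=row["source"],
            citation=row.get("citation", ""),
        )
        for _, row in df.iterrows()
    ]


def read_transporter_table(path: Path) -> List[TransporterEntry]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        TransporterEntry(
            species=row["species_id"],
            compartment_a=row["compartment_a"],
            compartment_b=row["compartment_b"],
            reversible=bool(row["reversible"]) if not isinstance(row["reversible"], str)
            else row["reversible"].strip().lower() in ("1", "true", "yes"),
            cotransport=row.get("cotransport", ""),
        )
        for _, row in df.iterrows()
    ]
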