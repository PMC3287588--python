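"""Core data model for compartmentalized stoichiometric networks.

A model is a collection of :class:`Metabolite` and :class:`Reaction` objects
spanning up to four cellular compartments (cytosol, plastid, mitochondrion,
microbody) plus the extracellular space.  The convention throughout the
package is that the same chemical species in two compartments is represented
by two distinct metabolites whose ids carry a compartment suffix
(``_c``, ``_p``, ``_m``, ``_x``, ``_e``).

Fluxes are expressed in mmol gDW^-1 h^-1; growth and drain pseudo-fluxes in
h^-1 equivalents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "COMPARTMENT_SUFFIX",
    "REACTION_KINDS",
    "EVIDENCE_KINDS",
    "Metabolite",
    "Reaction",
    "CompartmentalizedModel",
    "BiomassComposition",
    "ModelValidationError",
    "parse_formula",
    "formula_to_hill",
    "build_stoichiometric_matrix",
    "model_from_matrix",
    "add_biomass_equation",
    "elemental_balance_audit",
    "gpr_genes",
    "parse_reaction_equation",
    "format_reaction_equation",
]

#: Allowed compartment labels (four cellular plus extracellular).
COMPARTMENTS = ("cytosol", "plastid", "mitochondrion", "microbody", "extracellular")

#: Canonical id suffix per compartment.
COMPARTMENT_SUFFIX = {
    "cytosol": "c",
    "plastid": "p",
    "mitochondrion": "m",
    "microbody": "x",
    "extracellular": "e",
}
SUFFIX_COMPARTMENT = {v: k for k, v in COMPARTMENT_SUFFIX.items()}

REACTION_KINDS = (
    "enzymatic",
    "transport",
    "exchange",
    "biomass_drain",
    "non_enzymatic_gap",
)

EVIDENCE_KINDS = ("literature", "homolog", "default_cytosol", "not_applicable")

#: Conventional "effectively unbounded" flux box.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A structural problem in a model, reaction, or metabolite."""


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation elemental formula into an element -> count map.

    The empty string denotes a massless species (e.g. a photon) and parses to
    an empty map.  Raises ``ValueError`` on anything that is not a plain
    sequence of element symbols with optional integer counts.
    """
    if formula is None:
        raise ValueError("formula is None")
    formula = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def formula_to_hill(counts: Mapping[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    parts: List[str] = []
    keys = sorted(counts)
    ordered = [k for k in ("C", "H") if k in counts] + [
        k for k in keys if k not in ("C", "H")
    ]
    for k in ordered:
        n = counts[k]
        if n == 0:
            continue
        parts.append(k if n == 1 else f"{k}{n}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    """A chemical species bound to one compartment.

    ``id`` is unique within a model and encodes the compartment as a suffix;
    ``formula`` is an optional Hill-notation elemental composition (the empty
    string means massless, ``None`` means unknown).
    """

    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.formula is not None:
            parse_formula(self.formula)  # raises on malformed input

    @property
    def elements(self) -> Optional[Dict[str, int]]:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion over compartmentalized metabolites.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``gene_association`` is an infix boolean expression over gene
    identifiers using ``and`` / ``or`` and parentheses; the empty string means
    no known gene.
    """

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    reversible: bool = False
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    gene_association: str = ""
    kind: str = "enzymatic"
    compartment_evidence: str = "not_applicable"
    subsystem: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        lb, ub = self.lower_bound, self.upper_bound
        if lb is None:
            lb = -DEFAULT_BOUND if self.reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        object.__setattr__(self, "lower_bound", float(lb))
        object.__setattr__(self, "upper_bound", float(ub))
        self._check()

    def _check(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.compartment_evidence not in EVIDENCE_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown evidence {self.compartment_evidence!r}"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"reaction {self.id!r}: irreversible but lower_bound "
                f"{self.lower_bound} < 0"
            )
        if self.kind == "non_enzymatic_gap" and self.gene_association.strip():
            raise ModelValidationError(
                f"reaction {self.id!r}: non-enzymatic gap carries a gene association"
            )
        gpr_genes(self.gene_association)  # raises on malformed expressions

    @property
    def metabolite_ids(self) -> Tuple[str, ...]:
        return tuple(sorted(self.stoichiometry))

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(
            self,
            lower_bound=lower,
            upper_bound=upper,
            reversible=self.reversible or lower < 0,
        )

    def canonical_stoichiometry(self) -> Tuple[Tuple[str, float], ...]:
        """Stoichiometry in canonical (sorted) order, for duplicate detection."""
        return tuple(sorted((k, float(v)) for k, v in self.stoichiometry.items()))


@dataclass(frozen=True)
class BiomassComposition:
    """Per-condition biomass composition: component id -> coefficient.

    Coefficients are mmol of precursor consumed per gram of new dry weight;
    ``atp_maintenance`` is the growth-associated ATP cost in mmol gDW^-1.
    """

    condition: str
    coefficients: Mapping[str, float]
    atp_maintenance: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        if not any(v > 0 for v in self.coefficients.values()):
            raise ModelValidationError(
                "biomass composition needs at least one positive coefficient"
            )
        if any(v < 0 for v in self.coefficients.values()):
            raise ModelValidationError("biomass coefficients must be non-negative")


class CompartmentalizedModel:
    """The full network: compartments, metabolites, reactions, drains."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_components: Iterable[str] = (),
        biomass_reaction: Optional[str] = None,
        id: str = "model",
        name: str = "",
    ) -> None:
        self.id = id
        self.name = name
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.biomass_components: List[str] = list(biomass_components)
        self.biomass_reaction = biomass_reaction
        self.knockout_record: Dict[str, Tuple[float, float]] = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelValidationError(
                f"reaction {rxn.id!r} references unknown metabolites: {missing}"
            )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions.pop(rxn_id)
        except KeyError:
            raise ModelValidationError(f"unknown reaction {rxn_id!r}") from None

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reactions.get(rxn_id)
        if rxn is None:
            raise ModelValidationError(f"unknown reaction {rxn_id!r}")
        self.reactions[rxn_id] = rxn.with_bounds(lower, upper)

    def copy(self) -> "CompartmentalizedModel":
        new = CompartmentalizedModel(id=self.id, name=self.name)
        new.metabolites = dict(self.metabolites)
        new.reactions = dict(self.reactions)
        new.biomass_components = list(self.biomass_components)
        new.biomass_reaction = self.biomass_reaction
        new.knockout_record = dict(self.knockout_record)
        return new

    # -- views --------------------------------------------------------------

    @property
    def metabolite_ids(self) -> List[str]:
        return sorted(self.metabolites)

    @property
    def reaction_ids(self) -> List[str]:
        return sorted(self.reactions)

    @property
    def compartments(self) -> List[str]:
        return sorted({m.compartment for m in self.metabolites.values()})

    def reactions_of_kind(self, kind: str) -> List[Reaction]:
        return [r for r in (self.reactions[i] for i in self.reaction_ids) if r.kind == kind]

    def reaction_compartments(self, rxn: Reaction) -> List[str]:
        return sorted({self.metabolites[m].compartment for m in rxn.stoichiometry})

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError on failure."""
        seen_stoich: Dict[Tuple[Tuple[str, float], ...], str] = {}
        for rid in self.reaction_ids:
            rxn = self.reactions[rid]
            comps = self.reaction_compartments(rxn)
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange {rid!r} must touch exactly one metabolite"
                    )
                (mid,) = rxn.stoichiometry
                if self.metabolites[mid].compartment != "extracellular":
                    raise ModelValidationError(
                        f"exchange {rid!r} touches non-extracellular species {mid!r}"
                    )
            if rxn.kind == "transport" and len(comps) != 2:
                raise ModelValidationError(
                    f"transport {rid!r} must span exactly two compartments, "
                    f"spans {comps}"
                )
            key = rxn.canonical_stoichiometry()
            if key in seen_stoich:
                raise ModelValidationError(
                    f"reactions {seen_stoich[key]!r} and {rid!r} have identical "
                    "stoichiometry"
                )
            seen_stoich[key] = rid
        for cid in self.biomass_components:
            if cid not in self.reactions:
                raise ModelValidationError(f"biomass component drain {cid!r} missing")
        if self.biomass_reaction is not None and self.biomass_reaction not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} missing"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(
    model: CompartmentalizedModel,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Assemble the stoichiometric matrix S.

    Rows are metabolites, columns reactions, both in sorted-id order;
    ``S[i, j]`` is the signed coefficient of metabolite i in reaction j.
    Returns ``(S, metabolite_ids, reaction_ids)``.
    """
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            try:
                S[met_index[mid], j] = coeff
            except KeyError:
                raise ModelValidationError(
                    f"reaction {rid!r} references unknown metabolite {mid!r}"
                ) from None
    return S, met_ids, rxn_ids


def model_from_matrix(
    S: np.ndarray,
    metabolite_ids: List[str],
    reaction_ids: List[str],
    template: Optional[CompartmentalizedModel] = None,
) -> CompartmentalizedModel:
    """Rebuild a model from S plus its row/column orderings.

    When ``template`` is given, metabolite/reaction attributes other than the
    stoichiometry are taken from it; otherwise compartments are inferred from
    id suffixes.
    """
    mets = []
    for mid in metabolite_ids:
        if template is not None and mid in template.metabolites:
            mets.append(template.metabolites[mid])
        else:
            suffix = mid.rsplit("_", 1)[-1]
            comp = SUFFIX_COMPARTMENT.get(suffix, "cytosol")
            mets.append(Metabolite(id=mid, compartment=comp))
    rxns = []
    for j, rid in enumerate(reaction_ids):
        stoich = {
            metabolite_ids[i]: float(S[i, j])
            for i in range(len(metabolite_ids))
            if S[i, j] != 0.0
        }
        if template is not None and rid in template.reactions:
            rxns.append(replace(template.reactions[rid], stoichiometry=stoich))
        else:
            rxns.append(Reaction(id=rid, stoichiometry=stoich, reversible=True))
    model = CompartmentalizedModel(mets, rxns)
    if template is not None:
        model.biomass_components = list(template.biomass_components)
        model.biomass_reaction = template.biomass_reaction
        model.id, model.name = template.id, template.name
    return model


def add_biomass_equation(
    model: CompartmentalizedModel,
    composition: BiomassComposition,
    reaction_id: str = "BIOMASS",
    deactivate_drains: bool = True,
) -> CompartmentalizedModel:
    """Append a combined irreversible biomass synthesis equation.

    Each component id may name either a metabolite or an existing single-
    species drain reaction (in which case the drained metabolite is used).
    Individual component drains remain present but are bounded to zero once
    the combined equation is active, so a scenario runs in exactly one of the
    two modes (producibility screening via drains, growth via the combined
    equation).
    """
    new = model.copy()
    stoich: Dict[str, float] = {}
    missing: List[str] = []
    for comp_id, coeff in sorted(composition.coefficients.items()):
        if comp_id in new.metabolites:
            mid = comp_id
        elif comp_id in new.reactions and len(new.reactions[comp_id].stoichiometry) == 1:
            (mid,) = new.reactions[comp_id].stoichiometry
        else:
            missing.append(comp_id)
            continue
        stoich[mid] = stoich.get(mid, 0.0) - float(coeff)
    if missing:
        raise ModelValidationError(
            f"biomass components not in model: {sorted(missing)}"
        )
    if composition.atp_maintenance > 0:
        # growth-associated maintenance: hydrolyse ATP in the cytosol
        gam = float(composition.atp_maintenance)
        for mid, c in (("atp_c", -gam), ("h2o_c", -gam), ("adp_c", gam), ("pi_c", gam)):
            if mid not in new.metabolites:
                raise ModelValidationError(
                    f"ATP maintenance requires metabolite {mid!r} in the model"
                )
            stoich[mid] = stoich.get(mid, 0.0) + c
    rxn = Reaction(
        id=reaction_id,
        name=f"biomass synthesis ({composition.condition})",
        stoichiometry=stoich,
        reversible=False,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        kind="biomass_drain",
        compartment_evidence="not_applicable",
        subsystem="biomass",
    )
    new.add_reaction(rxn)
    new.biomass_reaction = reaction_id
    if deactivate_drains:
        for drain_id in new.biomass_components:
            new.set_bounds(drain_id, 0.0, 0.0)
    return new


@dataclass(frozen=True)
class BalanceReport:
    """Per-element residual of one reaction (positive = net produced)."""

    reaction_id: str
    status: str  # "balanced", "unbalanced", "unknown", "exempt"
    residual: Dict[str, float] = field(default_factory=dict)


def elemental_balance_audit(
    reaction: Reaction,
    formula_table: Mapping[str, Optional[str]],
    tolerance: float = 1e-9,
) -> BalanceReport:
    """Audit one reaction for elemental conservation.

    Exchange, biomass-drain and single-species demand reactions are exempt.
    If any participant lacks a formula the reaction is reported as
    ``unknown`` rather than ``unbalanced``.
    """
    if reaction.kind in ("exchange", "biomass_drain") or len(reaction.stoichiometry) == 1:
        return BalanceReport(reaction.id, "exempt")
    residual: Dict[str, float] = {}
    for mid, coeff in reaction.stoichiometry.items():
        formula = formula_table.get(mid)
        if formula is None:
            return BalanceReport(reaction.id, "unknown")
        for element, n in parse_formula(formula).items():
            residual[element] = residual.get(element, 0.0) + coeff * n
    residual = {e: v for e, v in residual.items() if abs(v) > tolerance}
    status = "balanced" if not residual else "unbalanced"
    return BalanceReport(reaction.id, status, residual)


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def gpr_genes(expression: str) -> List[str]:
    """Extract the sorted set of gene identifiers from a boolean GPR string.

    The grammar is infix boolean with ``and`` / ``or`` (case-insensitive) and
    parentheses.  Raises ``ModelValidationError`` on unbalanced parentheses.
    """
    if not expression or not expression.strip():
        return []
    depth = 0
    genes = set()
    for tok in _GPR_TOKEN.findall(expression):
        if tok == "(":
            depth += 1
        elif tok == ")":
            depth -= 1
            if depth < 0:
                raise ModelValidationError(f"unbalanced GPR expression {expression!r}")
        elif tok.lower() in ("and", "or"):
            continue
        else:
            genes.add(tok)
    if depth != 0:
        raise ModelValidationError(f"unbalanced GPR expression {expression!r}")
    return sorted(genes)


# ---------------------------------------------------------------------------
# textual reaction equations (tab-delimited interchange format)
# ---------------------------------------------------------------------------

_ARROW_REV = "<=>"
_ARROW_IRR = "-->"


def parse_reaction_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"a + 2 b <=> c"`` into a stoichiometry map and reversibility."""
    if _ARROW_REV in text:
        left, right = text.split(_ARROW_REV)
        reversible = True
    elif _ARROW_IRR in text:
        left, right = text.split(_ARROW_IRR)
        reversible = False
    else:
        raise ValueError(f"equation {text!r} lacks an arrow ({_ARROW_REV}/{_ARROW_IRR})")
    stoich: Dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, mid = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, mid = 1.0, parts[0]
            else:
                raise ValueError(f"malformed term {term!r} in equation {text!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    _accumulate(left, -1.0)
    _accumulate(right, +1.0)
    return {k: v for k, v in stoich.items() if v != 0.0}, reversible


def _fmt_coeff(c: float) -> str:
    return f"{c:g}"


def format_reaction_equation(stoich: Mapping[str, float], reversible: bool) -> str:
    """Inverse of :func:`parse_reaction_equation` (sorted, canonical)."""
    lhs = [
        (mid, -c) for mid, c in sorted(stoich.items()) if c < 0
    ]
    rhs = [(mid, c) for mid, c in sorted(stoich.items()) if c > 0]

    def _side(terms: List[Tuple[str, float]]) -> str:
        out = []
        for mid, c in terms:
            out.append(mid if c == 1.0 else f"{_fmt_coeff(c)} {mid}")
        return " + ".join(out)

    arrow = _ARROW_REV if reversible else _ARROW_IRR
    return f"{_side(lhs)} {arrow} {_side(rhs)}".strip()
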