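"""Producibility screening, dead-end detection and breakpoint tracing.

When a biomass component cannot be produced under a growth condition the
cause is a network gap: a missing producer, a blocked precursor further
upstream, a missing transporter stranding the species in another
compartment, or an irreversibility constraint pointing the wrong way.
:func:`trace_breakpoints` walks backwards from the blocked component over
producing reactions, testing each frontier metabolite with a producibility
LP, and returns the nearest blocked precursors with a cause label — the
sequential tracing used when closing gaps during curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .core import CompartmentalizedModel, Metabolite, Reaction
from .fba import FBAError, solve_fba
from .scenarios import apply_condition

__all__ = [
    "GapReport",
    "Breakpoint",
    "producibility_screen",
    "find_dead_ends",
    "trace_breakpoints",
]

#: production rates above this count as producible
PRODUCIBILITY_TOL = 1e-6

#: breadth-first tracing depth cap (keeps tracing desk-scale)
MAX_TRACE_DEPTH = 25

CAUSES = (
    "no_producer",
    "no_consumer",
    "blocked_precursor",
    "missing_transporter",
    "irreversibility_conflict",
)


@dataclass(frozen=True)
class Breakpoint:
    metabolite_id: str
    cause: str
    detail: str = ""


@dataclass(frozen=True)
class GapReport:
    """Producibility outcome for one biomass component."""

    component: str
    max_rate: float
    blocked: bool
    breakpoints: Tuple[Breakpoint, ...] = field(default_factory=tuple)


def _screening_bounds(
    model: CompartmentalizedModel, target_drain: str
) -> Dict[str, Tuple[float, float]]:
    """Drain-mode bounds: combined biomass off, other component drains off."""
    bounds: Dict[str, Tuple[float, float]] = {}
    if model.biomass_reaction and model.biomass_reaction in model.reactions:
        bounds[model.biomass_reaction] = (0.0, 0.0)
    for drain in model.biomass_components:
        if drain in model.reactions:
            bounds[drain] = (0.0, 0.0)
    if target_drain is not None:
        bounds[target_drain] = (0.0, 1000.0)
    return bounds


def producibility_screen(
    model: CompartmentalizedModel,
    components: Optional[Sequence[str]] = None,
    condition: Optional[str] = None,
) -> List[GapReport]:
    """Maximize each biomass-component drain; flag blocked components.

    ``components`` defaults to the model's drain list.  ``condition``
    optionally applies a trophic constraint set first (screening itself does
    not fix growth).
    """
    work = model
    if condition is not None:
        work, _spec = apply_condition(model, condition)
    if components is None:
        components = list(work.biomass_components)
    reports = []
    for drain in components:
        if drain not in work.reactions:
            raise FBAError(f"component drain {drain!r} not in model")
        dist = solve_fba(
            work, drain, sense="max", extra_bounds=_screening_bounds(work, drain)
        )
        rate = dist.objective_value if dist.optimal else 0.0
        reports.append(
            GapReport(component=drain, max_rate=rate,
                      blocked=rate <= PRODUCIBILITY_TOL)
        )
    return reports


def find_dead_ends(
    model: CompartmentalizedModel,
) -> Tuple[List[str], List[str]]:
    """Structural scan for never-produced and never-consumed metabolites.

    Directionality-aware and iterated to a fixpoint: a reaction produces a
    metabolite if a positive coefficient can carry positive flux (or a
    negative one can run backwards), but a multi-species reaction can only
    carry steady-state flux at all if every metabolite it touches is also
    touched by some other active reaction — an isolated reversible pair with
    neither source nor sink is therefore dead in both directions.  Exchange
    and drain reactions count as producers/consumers of their species.
    """
    active: Set[str] = set(model.reaction_ids)
    while True:
        touches: Dict[str, int] = {}
        for rid in active:
            for mid in model.reactions[rid].stoichiometry:
                touches[mid] = touches.get(mid, 0) + 1
        dropped = {
            rid
            for rid in active
            if len(model.reactions[rid].stoichiometry) > 1
            and any(touches[mid] < 2 for mid in model.reactions[rid].stoichiometry)
        }
        if not dropped:
            break
        active -= dropped
    producible: Set[str] = set()
    consumable: Set[str] = set()
    for rid in sorted(active):
        rxn = model.reactions[rid]
        for mid, coeff in rxn.stoichiometry.items():
            if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
                producible.add(mid)
            if (coeff < 0 and rxn.upper_bound > 0) or (coeff > 0 and rxn.lower_bound < 0):
                consumable.add(mid)
    all_ids = set(model.metabolite_ids)
    never_produced = sorted(all_ids - producible)
    never_consumed = sorted(all_ids - consumable)
    return never_produced, never_consumed


def _structural_producers(
    model: CompartmentalizedModel, mid: str
) -> List[Tuple[str, int]]:
    """Reactions that can produce ``mid`` under current bounds.

    Returns (reaction id, direction) with direction +1 for forward
    production, -1 for reverse.
    """
    out = []
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        coeff = rxn.stoichiometry.get(mid)
        if coeff is None:
            continue
        if coeff > 0 and rxn.upper_bound > 0:
            out.append((rid, +1))
        elif coeff < 0 and rxn.lower_bound < 0:
            out.append((rid, -1))
    return out


def _locked_producers(model: CompartmentalizedModel, mid: str) -> List[str]:
    """Reactions whose stoichiometry could produce ``mid`` if their
    irreversibility constraint were relaxed."""
    out = []
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        coeff = rxn.stoichiometry.get(mid)
        if coeff is None:
            continue
        if coeff < 0 and rxn.lower_bound >= 0 and rxn.upper_bound > 0:
            out.append(rid)
        elif coeff > 0 and rxn.upper_bound <= 0 and rxn.lower_bound < 0:
            out.append(rid)
    return out


def _producible(model: CompartmentalizedModel, mid: str) -> bool:
    """LP test: can a demand on ``mid`` carry flux above tolerance?"""
    probe_id = "__DM_probe__"
    work = model.copy()
    work.add_reaction(
        Reaction(id=probe_id, stoichiometry={mid: -1.0}, reversible=False,
                 lower_bound=0.0, upper_bound=1000.0, kind="biomass_drain")
    )
    dist = solve_fba(work, probe_id, sense="max",
                     extra_bounds=_screening_bounds(work, probe_id))
    return dist.optimal and dist.objective_value > PRODUCIBILITY_TOL


def _sibling_compartment_ids(model: CompartmentalizedModel, mid: str) -> List[str]:
    base = mid.rsplit("_", 1)[0]
    return [
        other
        for other in model.metabolite_ids
        if other != mid and other.rsplit("_", 1)[0] == base
    ]


def _has_transport_link(model: CompartmentalizedModel, mid: str, other: str) -> bool:
    for rid in model.reaction_ids:
        rxn = model.reactions[rid]
        if rxn.kind != "transport":
            continue
        s = rxn.stoichiometry
        if mid in s and other in s:
            # can it move toward mid?
            coeff = s[mid]
            if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
                return True
    return False


def _classify(model: CompartmentalizedModel, mid: str) -> Optional[Breakpoint]:
    """Assign a cause to a non-producible metabolite (None: recurse deeper).

    Order: structural no-producer first (refined to irreversibility_conflict
    or missing_transporter when evidence supports those), then
    blocked_precursor for metabolites whose producers exist but are starved.
    """
    # a sibling-compartment pool that is producible but unlinked is the most
    # specific evidence and takes precedence
    for other in _sibling_compartment_ids(model, mid):
        if not _has_transport_link(model, mid, other) and _producible(model, other):
            return Breakpoint(
                mid, "missing_transporter",
                f"producible as {other} but no transport into this compartment",
            )
    producers = _structural_producers(model, mid)
    if not producers:
        genuinely_locked = []
        for rid in _locked_producers(model, mid):
            relaxed = model.copy()
            relaxed.set_bounds(rid, -abs(relaxed.reactions[rid].upper_bound or 1000.0),
                               abs(relaxed.reactions[rid].upper_bound or 1000.0))
            if _producible(relaxed, mid):
                genuinely_locked.append(rid)
        if genuinely_locked:
            return Breakpoint(mid, "irreversibility_conflict",
                              f"producers locked by irreversibility: {sorted(genuinely_locked)}")
        return Breakpoint(mid, "no_producer", "no reaction can produce this species")
    return None  # blocked precursor(s) upstream — caller recurses


def trace_breakpoints(
    model: CompartmentalizedModel,
    component: str,
    condition: Optional[str] = None,
    max_depth: int = MAX_TRACE_DEPTH,
) -> List[Breakpoint]:
    """Trace the nearest blocked precursors of a blocked biomass component.

    Backward breadth-first traversal from the component over producing
    reactions; at each frontier metabolite a producibility LP decides
    blocked/producible, and the first blocked metabolites that admit a cause
    label are returned.  Deterministic (sorted frontier) and cycle-safe.
    """
    work = model
    if condition is not None:
        work, _spec = apply_condition(model, condition)
    if component in work.reactions:
        drain = work.reactions[component]
        if len(drain.stoichiometry) != 1:
            raise FBAError(f"{component!r} is not a single-species drain")
        (start,) = drain.stoichiometry
    elif component in work.metabolites:
        start = component
    else:
        raise FBAError(f"unknown component {component!r}")
    if _producible(work, start):
        raise FBAError(f"component {component!r} is producible — nothing to trace")

    visited: Set[str] = set()
    frontier: List[str] = [start]
    found: List[Breakpoint] = []
    depth = 0
    while frontier and depth < max_depth:
        next_frontier: List[str] = []
        for mid in sorted(frontier):
            if mid in visited:
                continue
            visited.add(mid)
            if _producible(work, mid):
                continue
            bp = _classify(work, mid)
            if bp is not None:
                found.append(bp)
                # a missing transporter is one possible repair, but the root
                # cause may sit deeper on the producing branch — keep walking
                if bp.cause != "missing_transporter":
                    continue
            # recurse into substrates of the structural producers
            for rid, direction in _structural_producers(work, mid):
                rxn = work.reactions[rid]
                for sub, coeff in sorted(rxn.stoichiometry.items()):
                    consumed = coeff < 0 if direction > 0 else coeff > 0
                    if consumed and sub not in visited:
                        next_frontier.append(sub)
            if not any(True for _ in _structural_producers(work, mid)):
                continue
            # mark the hop itself so the component's own report is informative
            if depth == 0 and not found:
                pass
        frontier = next_frontier
        depth += 1
    if not found:
        found.append(
            Breakpoint(start, "blocked_precursor",
                       "all upstream precursors blocked within trace depth")
        )
    # deduplicate, preserve deterministic order
    seen = set()
    unique = []
    for bp in sorted(found, key=lambda b: (b.metabolite_id, b.cause)):
        key = (bp.metabolite_id, bp.cause)
        if key not in seen:
            seen.add(key)
            unique.append(bp)
    return unique
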