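"""Flux balance analysis: the linear-programming core.

Steady-state flux distributions solve

    max/min  c . v
    s.t.     S v = 0,   lb <= v <= ub

with S the stoichiometric matrix.  Problems are solved with the HiGHS
simplex through :func:`scipy.optimize.linprog`.

Because FBA optima are typically degenerate, the scalar objective value is
the contract of every operation here; reported flux *vectors* additionally
minimize the sum of absolute fluxes at the fixed optimum (a secondary LP,
the standard parsimonious resolution), which makes flux comparisons between
scenarios reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import CompartmentalizedModel, build_stoichiometric_matrix

__all__ = [
    "FluxDistribution",
    "ScenarioSpec",
    "FBAError",
    "solve_fba",
    "minimize_substrate",
    "maximize_product",
    "knockout",
]

#: solver tolerance and the looser tolerance used for feasibility reporting
SOLVER_TOL = 1e-9
FEASIBILITY_TOL = 1e-6


class FBAError(ValueError):
    """Usage error in an FBA call (unknown reaction, empty model, ...)."""


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state solution.

    ``fluxes`` maps reaction id to its flux in mmol gDW^-1 h^-1 (growth and
    drain pseudo-fluxes in h^-1 equivalents).  ``status`` is one of
    ``optimal``, ``infeasible``, ``unbounded``.
    """

    fluxes: Dict[str, float]
    objective_value: float
    objective_reaction: str
    status: str
    binding_constraints: Tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def residual(self, model: CompartmentalizedModel) -> float:
        """max |S v| — the steady-state mass-balance violation."""
        S, met_ids, rxn_ids = build_stoichiometric_matrix(model)
        v = np.array([self.fluxes.get(r, 0.0) for r in rxn_ids])
        if S.size == 0:
            return 0.0
        return float(np.max(np.abs(S @ v)))

    def to_series(self):
        import pandas as pd

        return pd.Series(self.fluxes, name="flux").sort_index()


@dataclass(frozen=True)
class ScenarioSpec:
    """A trophic condition in machine form.

    ``bound_overrides`` maps reaction id to a (lower, upper) pair applied on
    top of the model defaults; ``fixed_growth_rate`` pins the biomass
    reaction (equality, lb = ub).  ``objective_1`` is the resource-efficiency
    objective (substrate exchange, minimized uptake); ``objective_2`` the
    optional bio-product objective.
    """

    condition: str
    bound_overrides: Mapping[str, Tuple[float, float]]
    fixed_growth_rate: float
    objective_1: Tuple[str, str]  # (reaction id, "minimize"|"maximize")
    objective_2: Optional[Tuple[str, str]] = None
    substrate_exchange: str = ""
    product_exchange: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound_overrides", dict(self.bound_overrides))
        if self.fixed_growth_rate < 0:
            raise FBAError("fixed_growth_rate must be non-negative")
        for rid, (lb, ub) in self.bound_overrides.items():
            if lb > ub:
                raise FBAError(f"override for {rid!r} has lower > upper")


def _apply_bounds(
    model: CompartmentalizedModel,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]],
) -> CompartmentalizedModel:
    if not extra_bounds:
        return model
    out = model.copy()
    for rid, (lb, ub) in extra_bounds.items():
        if rid not in out.reactions:
            raise FBAError(f"bound override references unknown reaction {rid!r}")
        rxn = out.reactions[rid]
        out.reactions[rid] = rxn.with_bounds(lb, ub)
    return out


def _linprog_status(result) -> str:
    if result.status == 0:
        return "optimal"
    if result.status == 2:
        return "infeasible"
    if result.status == 3:
        return "unbounded"
    return "infeasible"


def solve_fba(
    model: CompartmentalizedModel,
    objective: str,
    sense: str = "max",
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    parsimonious: bool = False,
) -> FluxDistribution:
    """Solve one FBA problem; infeasibility is a status, never an exception.

    With ``parsimonious=True`` a second LP minimizes the total absolute flux
    at the fixed optimum so the returned vector is a reproducible
    representative of the optimal face.
    """
    if not model.reactions:
        raise FBAError("model has no reactions")
    if objective not in model.reactions:
        raise FBAError(f"unknown objective reaction {objective!r}")
    if sense not in ("max", "min"):
        raise FBAError(f"sense must be 'max' or 'min', got {sense!r}")
    work = _apply_bounds(model, extra_bounds)
    S, met_ids, rxn_ids = build_stoichiometric_matrix(work)
    n = len(rxn_ids)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    lb = np.array([work.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([work.reactions[r].upper_bound for r in rxn_ids])
    c = np.zeros(n)
    c[idx[objective]] = -1.0 if sense == "max" else 1.0

    res = linprog(
        c,
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    status = _linprog_status(res)
    if status != "optimal":
        binding = _diagnose_binding(work, rxn_ids)
        return FluxDistribution({}, float("nan"), objective, status, binding)

    opt = float(res.x[idx[objective]])
    v = res.x
    if parsimonious:
        v = _parsimonious(S, lb, ub, idx[objective], opt, v)
    fluxes = {r: float(v[idx[r]]) for r in rxn_ids}
    return FluxDistribution(fluxes, opt, objective, "optimal")


def _parsimonious(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    obj_idx: int,
    opt: float,
    fallback: np.ndarray,
) -> np.ndarray:
    """Minimize sum |v| subject to S v = 0, bounds, and v[obj] = opt."""
    n = len(lb)
    # split v = v_plus - v_minus
    lb_p = np.maximum(lb, 0.0)
    ub_p = np.maximum(ub, 0.0)
    lb_m = np.maximum(-ub, 0.0)
    ub_m = np.maximum(-lb, 0.0)
    A_eq = np.hstack([S, -S]) if S.size else np.zeros((0, 2 * n))
    b_eq = np.zeros(A_eq.shape[0])
    fix = np.zeros(2 * n)
    fix[obj_idx] = 1.0
    fix[n + obj_idx] = -1.0
    A_eq = np.vstack([A_eq, fix])
    b_eq = np.append(b_eq, opt)
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(np.concatenate([lb_p, lb_m]), np.concatenate([ub_p, ub_m]))),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status != 0:  # numerically tight optimum: keep the primary vertex
        return fallback
    return res.x[:n] - res.x[n:]


def _diagnose_binding(model: CompartmentalizedModel, rxn_ids) -> Tuple[str, ...]:
    """Heuristic report of fixed (lb == ub) constraints for infeasible LPs."""
    return tuple(
        r
        for r in rxn_ids
        if model.reactions[r].lower_bound == model.reactions[r].upper_bound
        and model.reactions[r].lower_bound != 0.0
    )


def _fix_growth(
    model: CompartmentalizedModel, scenario: ScenarioSpec
) -> CompartmentalizedModel:
    growth_id = model.biomass_reaction
    if growth_id is None:
        raise FBAError("model has no combined biomass reaction")
    bounds = dict(scenario.bound_overrides)
    bounds[growth_id] = (scenario.fixed_growth_rate, scenario.fixed_growth_rate)
    return _apply_bounds(model, bounds)


def minimize_substrate(
    model: CompartmentalizedModel, scenario: ScenarioSpec
) -> FluxDistribution:
    """Minimize uptake of the scenario's key substrate at fixed growth.

    With the sign convention that exchange flux < 0 is uptake, minimizing
    uptake magnitude equals maximizing the (non-positive) exchange flux.
    The returned distribution is parsimonious.
    """
    if not scenario.substrate_exchange:
        raise FBAError("scenario does not name a substrate exchange")
    work = _fix_growth(model, scenario)
    return solve_fba(work, scenario.substrate_exchange, sense="max",
                     parsimonious=True)


def maximize_product(
    model: CompartmentalizedModel,
    scenario: ScenarioSpec,
    product: str,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxDistribution:
    """Maximize a product exchange at fixed growth.

    ``extra_bounds`` carries scenario-specific pins (e.g. substrate uptake
    fixed at its substrate-minimal optimum) and is applied on top of the
    scenario overrides.
    """
    work = _fix_growth(model, scenario)
    work = _apply_bounds(work, extra_bounds)
    return solve_fba(work, product, sense="max", parsimonious=True)


def knockout(model: CompartmentalizedModel, reaction_ids) -> CompartmentalizedModel:
    """Return a copy with the listed reactions' bounds set to (0, 0).

    Original bounds are recorded in ``knockout_record`` for reversal.
    """
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    out = model.copy()
    for rid in reaction_ids:
        if rid not in out.reactions:
            raise FBAError(f"cannot knock out unknown reaction {rid!r}")
        rxn = out.reactions[rid]
        out.knockout_record[rid] = (rxn.lower_bound, rxn.upper_bound)
        out.reactions[rid] = rxn.with_bounds(0.0, 0.0)
    return out
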