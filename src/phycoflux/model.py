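"""Modelling facade: a fitted-model API over the FBA machinery.

:class:`FluxBalanceModel` wraps a :class:`~phycoflux.core.CompartmentalizedModel`
together with a trophic scenario; :meth:`FluxBalanceModel.fit` solves the
scenario's resource-efficiency program and returns a :class:`FBAResults`
object carrying the flux estimates, diagnostics and a ``summary()`` table,
in the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CompartmentalizedModel, build_stoichiometric_matrix
from .fba import (
    FBAError,
    FluxDistribution,
    ScenarioSpec,
    maximize_product,
    minimize_substrate,
    solve_fba,
)

__all__ = ["FluxBalanceModel", "FBAResults"]


class FluxBalanceModel:
    """A steady-state flux balance model under one trophic condition.

    Parameters
    ----------
    network :
        The compartmentalized metabolic network.
    condition :
        One of ``autotrophic``, ``heterotrophic``, ``mixotrophic``; bounds
        the exchanges accordingly.  ``None`` keeps the network's own bounds.
    growth_rate :
        Fixed specific growth rate (h^-1); defaults to the condition's
        standard rate.
    """

    def __init__(
        self,
        network: CompartmentalizedModel,
        condition: Optional[str] = None,
        growth_rate: Optional[float] = None,
    ) -> None:
        self.condition = condition
        if condition is not None:
            from .scenarios import apply_condition

            self.network, self.scenario = apply_condition(
                network, condition, growth_rate=growth_rate
            )
        else:
            self.network = network.copy()
            self.scenario = None

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_fixture(cls, condition: str = "autotrophic", **fixture_kwargs):
        """Build from the shipped synthetic algal core network."""
        from .fixtures import FixtureOptions, generate_core_network

        opts = FixtureOptions(**fixture_kwargs) if fixture_kwargs else None
        return cls(generate_core_network(opts), condition=condition)

    @classmethod
    def from_sbml(cls, path, condition: Optional[str] = None):
        from .sbml_io import read_sbml

        return cls(read_sbml(path), condition=condition)

    # -- fitting -------------------------------------------------------------

    def fit(self, objective: Optional[str] = None, sense: str = "max") -> "FBAResults":
        """Solve the scenario's LP and return results.

        Without an explicit objective the scenario's resource-efficiency
        program is solved (minimal substrate uptake at fixed growth); with
        one, that reaction is optimized at fixed growth.
        """
        if self.scenario is None:
            if objective is None:
                raise FBAError("no scenario: an explicit objective is required")
            dist = solve_fba(self.network, objective, sense=sense, parsimonious=True)
        elif objective is None:
            dist = minimize_substrate(self.network, self.scenario)
        else:
            dist = maximize_product(self.network, self.scenario, objective)
        return FBAResults(self, dist)

    def fit_maximize(self, product: str) -> "FBAResults":
        """Maximize a product exchange at fixed growth."""
        return self.fit(objective=product, sense="max")


class FBAResults:
    """Results of one flux balance fit."""

    def __init__(self, model: FluxBalanceModel, distribution: FluxDistribution):
        self.model = model
        self.distribution = distribution

    # -- accessors -----------------------------------------------------------

    @property
    def status(self) -> str:
        return self.distribution.status

    @property
    def objective_value(self) -> float:
        return self.distribution.objective_value

    @property
    def fluxes(self) -> pd.Series:
        return self.distribution.to_series()

    def __getitem__(self, reaction_id: str) -> float:
        return self.distribution.fluxes[reaction_id]

    # -- diagnostics ---------------------------------------------------------

    def steady_state_residual(self) -> float:
        return self.distribution.residual(self.model.network)

    def active_fluxes(self, atol: float = 1e-9) -> pd.Series:
        s = self.fluxes
        return s[s.abs() > atol]

    def flux_frame(self) -> pd.DataFrame:
        """Flux table with names, compartments and subsystems."""
        net = self.model.network
        rows = []
        for rid in net.reaction_ids:
            r = net.reactions[rid]
            rows.append(
                {
                    "reaction_id": rid,
                    "name": r.name,
                    "subsystem": r.subsystem,
                    "compartments": "/".join(net.reaction_compartments(r)),
                    "flux": self.distribution.fluxes.get(rid, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("reaction_id")

    def summary(self, top: int = 15) -> str:
        """Human-readable summary table."""
        net = self.model.network
        d = self.distribution
        lines = [
            "Flux Balance Analysis Results",
            "=" * 46,
            f"network:            {net.id} ({len(net.reactions)} reactions, "
            f"{len(net.metabolites)} metabolites)",
            f"condition:          {self.model.condition or '(custom bounds)'}",
            f"objective:          {d.objective_reaction}",
            f"status:             {d.status}",
        ]
        if d.optimal:
            lines += [
                f"objective value:    {d.objective_value:.6f}",
                f"steady-state |S v|: {self.steady_state_residual():.2e}",
                "-" * 46,
                f"largest fluxes (top {top}):",
            ]
            s = self.active_fluxes().abs().sort_values(ascending=False).head(top)
            for rid in s.index:
                lines.append(
                    f"  {rid:<22s} {d.fluxes[rid]:>12.4f}  "
                    f"{net.reactions[rid].subsystem}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<FBAResults {self.distribution.objective_reaction}="
            f"{self.distribution.objective_value:.4g} [{self.status}]>"
        )
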