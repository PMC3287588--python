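"""Trophic growth conditions and the comparative H2 flux experiments.

The three conditions apply the minimal constraint sets

==================  ===========  =============  ===========
constraint          autotrophic  heterotrophic  mixotrophic
==================  ===========  =============  ===========
CO2 uptake          +            -              +
acetate uptake      -            +              +
photon uptake       free         -              free
optimization 1      min photons  min acetate    min photons
optimization 2      max H2       max H2         max H2
growth rate (h^-1)  0.059        0.035          0.066
==================  ===========  =============  ===========

"-" closes the uptake bound only; secretion stays open where physiology
demands it (respiring cells must vent CO2 in the dark).  The dark condition
additionally caps O2 uptake (dark, oxygen-limited culture), which is what
makes fermentative overflow — and hence H2 — part of the solution space.

The H2 study (:func:`h2_study`) follows the two-optimality-criteria
protocol: the wild-type reference is the substrate-minimal flux distribution
at the condition's growth rate; the hypothetical producer maximizes H2 at
the same growth rate under a fixed illumination (light conditions) or a
fixed acetate supply (dark).  For knockout comparisons the baseline run
holds the targeted reactions at their wild-type operating flux — the
knockout run forces them to zero — so the predicted production increase is
attributable to releasing that wild-type constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import CompartmentalizedModel
from .fba import (
    FBAError,
    FluxDistribution,
    ScenarioSpec,
    knockout,
    maximize_product,
    minimize_substrate,
    solve_fba,
)

__all__ = [
    "CONDITIONS",
    "GROWTH_RATES",
    "apply_condition",
    "compare_fluxes",
    "FluxComparison",
    "h2_study",
    "H2StudyReport",
    "load_scenario",
    "preset_path",
]

CONDITIONS = ("autotrophic", "heterotrophic", "mixotrophic")

#: fixed specific growth rates per condition, h^-1
GROWTH_RATES = {"autotrophic": 0.059, "heterotrophic": 0.035, "mixotrophic": 0.066}

#: O2 uptake cap in the dark (oxygen-limited heterotrophic culture),
#: mmol gDW^-1 h^-1.  Above the growth requirement at 0.035 h^-1 (dark
#: growth on acetate is respiration-dependent) but low enough that
#: respiratory capacity, not acetate supply, bounds ATP regeneration.
DARK_O2_UPTAKE_MAX = 2.0

#: non-growth-associated ATP maintenance, mmol gDW^-1 h^-1
NGAM_ATP = 0.2

#: photon supply in the light H2 studies, expressed as a multiple of the
#: wild-type minimal photon demand: constant moderate illumination — enough
#: excess to divert into H2 without saturating, while keeping photon supply
#: scarce enough that the photosystem operating mode matters
ILLUMINATION_EXCESS = 2.5

#: heterotrophic H2 studies fix acetate slightly above the growth-minimal
#: uptake (the supply sweep regime); at the exact minimum every resource is
#: binding and no electrons are spare
DARK_SUBSTRATE_ALLOWANCE = 1.25


def _require(model: CompartmentalizedModel, rid: str) -> None:
    if rid not in model.reactions:
        raise FBAError(f"condition requires exchange reaction {rid!r}")


def apply_condition(
    model: CompartmentalizedModel,
    condition: str,
    growth_rate: Optional[float] = None,
) -> Tuple[CompartmentalizedModel, ScenarioSpec]:
    """Bound a model for one trophic condition and return the scenario spec.

    The returned model carries the condition's exchange bounds; growth is not
    yet fixed (the optimization entry points do that from the spec).
    """
    if condition not in CONDITIONS:
        raise FBAError(f"unknown condition {condition!r}")
    for rid in ("EX_photon_e", "EX_co2_e", "EX_ac_e", "EX_o2_e"):
        _require(model, rid)
    from .fixtures import ACETATE_UPTAKE_MAX

    overrides: Dict[str, Tuple[float, float]] = {}
    if condition == "autotrophic":
        overrides["EX_photon_e"] = (-1000.0, 0.0)
        overrides["EX_co2_e"] = (-1000.0, 1000.0)
        overrides["EX_ac_e"] = (0.0, 1000.0)
        overrides["EX_o2_e"] = (-1000.0, 1000.0)
        substrate = "EX_photon_e"
    elif condition == "heterotrophic":
        overrides["EX_photon_e"] = (0.0, 0.0)
        overrides["EX_co2_e"] = (0.0, 1000.0)
        overrides["EX_ac_e"] = (-ACETATE_UPTAKE_MAX, 1000.0)
        overrides["EX_o2_e"] = (-DARK_O2_UPTAKE_MAX, 1000.0)
        substrate = "EX_ac_e"
    else:  # mixotrophic
        overrides["EX_photon_e"] = (-1000.0, 0.0)
        overrides["EX_co2_e"] = (-1000.0, 1000.0)
        overrides["EX_ac_e"] = (-ACETATE_UPTAKE_MAX, 1000.0)
        overrides["EX_o2_e"] = (-1000.0, 1000.0)
        substrate = "EX_photon_e"
    if "ATPM_c" in model.reactions:
        overrides["ATPM_c"] = (NGAM_ATP, 1000.0)
    rate = GROWTH_RATES[condition] if growth_rate is None else growth_rate
    spec = ScenarioSpec(
        condition=condition,
        bound_overrides=overrides,
        fixed_growth_rate=rate,
        objective_1=(substrate, "minimize uptake"),
        objective_2=("EX_h2_e", "maximize"),
        substrate_exchange=substrate,
        product_exchange="EX_h2_e",
    )
    bounded = model.copy()
    for rid, (lb, ub) in overrides.items():
        bounded.set_bounds(rid, lb, ub)
    return bounded, spec


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------


def preset_path(condition: str):
    """Path of the shipped YAML preset for a trophic condition."""
    from importlib.resources import files

    if condition not in CONDITIONS:
        raise FBAError(f"unknown condition {condition!r}")
    return files("phycoflux") / "presets" / f"{condition}.yaml"


def load_scenario(source) -> ScenarioSpec:
    """Load a ScenarioSpec from a YAML/JSON scenario file.

    ``source`` may be a path or a condition name (which loads the shipped
    preset).  The file carries condition, bound overrides, the fixed growth
    rate and the two objectives.
    """
    import yaml

    if isinstance(source, str) and source in CONDITIONS:
        text = preset_path(source).read_text()
    else:
        from pathlib import Path

        text = Path(source).read_text()
    data = yaml.safe_load(text)
    overrides = {
        rid: (float(lo), float(hi))
        for rid, (lo, hi) in (data.get("bound_overrides") or {}).items()
    }
    obj1 = tuple(data["objective_1"])
    obj2 = tuple(data["objective_2"]) if data.get("objective_2") else None
    return ScenarioSpec(
        condition=data["condition"],
        bound_overrides=overrides,
        fixed_growth_rate=float(data["fixed_growth_rate"]),
        objective_1=obj1,
        objective_2=obj2,
        substrate_exchange=data.get("substrate_exchange", obj1[0]),
        product_exchange=data.get("product_exchange", ""),
    )


# ---------------------------------------------------------------------------
# flux comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluxComparison:
    """Per-reaction classification of a test vs. a reference distribution.

    A reaction is ``increased`` when |test| > (1+threshold)·|reference|
    (reference magnitudes below ``floor`` are floored), ``decreased`` when
    |test| < (1-threshold)·|reference|, else ``unchanged``.
    """

    classes: Dict[str, str]
    threshold: float
    floor: float

    def of_class(self, cls: str) -> List[str]:
        return sorted(r for r, c in self.classes.items() if c == cls)

    def counts(self) -> Dict[str, int]:
        out = {"increased": 0, "decreased": 0, "unchanged": 0}
        for c in self.classes.values():
            out[c] += 1
        return out


def compare_fluxes(
    reference: FluxDistribution,
    test: FluxDistribution,
    threshold: float = 0.20,
    floor: float = 1e-6,
) -> FluxComparison:
    """Classify each reaction's flux change (>20 % by default)."""
    ref_ids = set(reference.fluxes)
    test_ids = set(test.fluxes)
    if ref_ids != test_ids:
        diff = sorted(ref_ids ^ test_ids)
        raise FBAError(f"flux distributions cover different reactions: {diff}")
    classes: Dict[str, str] = {}
    for rid in reference.fluxes:
        ref = max(abs(reference.fluxes[rid]), floor)
        tst = abs(test.fluxes[rid])
        if tst > (1.0 + threshold) * ref:
            classes[rid] = "increased"
        elif tst < (1.0 - threshold) * ref:
            classes[rid] = "decreased"
        else:
            classes[rid] = "unchanged"
    return FluxComparison(classes, threshold, floor)


def _subsystem_direction(
    model: CompartmentalizedModel,
    reference: FluxDistribution,
    test: FluxDistribution,
    threshold: float = 0.20,
    floor: float = 1e-6,
) -> Dict[str, str]:
    """Aggregate +/-/0 direction of summed |flux| per pathway tag."""
    sums_ref: Dict[str, float] = {}
    sums_test: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if not rxn.subsystem or rid not in reference.fluxes:
            continue
        sums_ref[rxn.subsystem] = sums_ref.get(rxn.subsystem, 0.0) + abs(
            reference.fluxes[rid]
        )
        sums_test[rxn.subsystem] = sums_test.get(rxn.subsystem, 0.0) + abs(
            test.fluxes[rid]
        )
    out: Dict[str, str] = {}
    for sub in sorted(sums_ref):
        ref = max(sums_ref[sub], floor)
        tst = sums_test[sub]
        if tst > (1.0 + threshold) * ref:
            out[sub] = "+"
        elif tst < (1.0 - threshold) * ref:
            out[sub] = "-"
        else:
            out[sub] = "0"
    return out


# ---------------------------------------------------------------------------
# H2 study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class H2StudyReport:
    """Outcome of one comparative H2 experiment."""

    condition: str
    knockouts: Tuple[str, ...]
    substrate_minimum: float          # wild-type substrate uptake, mmol/gDW/h
    baseline_h2_max: float            # H2 max with wild-type operation
    knockout_h2_max: float            # H2 max with targets knocked out
    fold_change: float
    wildtype: FluxDistribution
    baseline: FluxDistribution
    after_knockout: Optional[FluxDistribution]
    comparison: FluxComparison
    direction_table: Dict[str, str]

    @property
    def h2_max(self) -> float:
        return (
            self.knockout_h2_max if self.knockouts else self.baseline_h2_max
        )

    def summary(self) -> str:
        lines = [
            f"H2 study — {self.condition} condition",
            f"  knockouts:            {', '.join(self.knockouts) or '(none)'}",
            f"  substrate minimum:    {self.substrate_minimum:.4f} mmol/gDW/h",
            f"  baseline max H2:      {self.baseline_h2_max:.4f} mmol/gDW/h",
        ]
        if self.knockouts:
            lines.append(
                f"  knockout max H2:      {self.knockout_h2_max:.4f} mmol/gDW/h"
            )
            lines.append(f"  fold change:          {self.fold_change:.2f}")
        lines.append("  pathway direction table (vs. wild type):")
        for sub, d in self.direction_table.items():
            lines.append(f"    {sub:<40s} {d}")
        return "\n".join(lines)


def h2_study(
    model: CompartmentalizedModel,
    condition: str,
    knockouts: Sequence[str] = (),
    illumination: Optional[float] = None,
    substrate_allowance: Optional[float] = None,
    threshold: float = 0.20,
) -> H2StudyReport:
    """Run the comparative H2 experiment for one trophic condition.

    Steps: (1) wild type — minimize substrate uptake at the condition's fixed
    growth rate; (2) baseline producer — maximize H2 with the substrate
    supply fixed (dark) or illumination capped (light), holding any knockout
    targets at their wild-type flux; (3) knockout producer — same with the
    targets at zero.  Reports the fold change and a per-pathway direction
    table of the producer relative to the wild type.

    ``illumination`` is the photon uptake cap for the producer runs (light
    conditions); by default it is ``ILLUMINATION_EXCESS`` times the wild-type
    minimal photon demand — constant, moderate light.
    """
    product = "EX_h2_e"
    if product not in model.reactions:
        raise FBAError("model lacks an H2 exchange reaction")
    bounded, spec = apply_condition(model, condition)
    for rid in knockouts:
        if rid not in model.reactions:
            raise FBAError(f"unknown knockout target {rid!r}")

    wt = minimize_substrate(bounded, spec)
    if not wt.optimal:
        raise FBAError(f"wild-type reference infeasible under {condition}")
    substrate_min = -wt.fluxes[spec.substrate_exchange]

    # producer-side bounds: fix the energy/carbon supply
    pins: Dict[str, Tuple[float, float]] = {}
    if condition == "heterotrophic":
        allowance = (
            DARK_SUBSTRATE_ALLOWANCE if substrate_allowance is None
            else substrate_allowance
        )
        supply = substrate_min * allowance
        pins[spec.substrate_exchange] = (-supply, -supply)
    else:
        cap = (
            substrate_min * ILLUMINATION_EXCESS
            if illumination is None
            else illumination
        )
        pins["EX_photon_e"] = (-cap, 0.0)

    base_pins = dict(pins)
    for rid in knockouts:
        base_pins[rid] = (wt.fluxes[rid], wt.fluxes[rid])
    baseline = maximize_product(bounded, spec, product, extra_bounds=base_pins)
    if not baseline.optimal:
        raise FBAError(f"baseline H2 maximization infeasible under {condition}")
    h_base = baseline.objective_value

    after = None
    h_ko = h_base
    if knockouts:
        ko_model = knockout(bounded, list(knockouts))
        after = maximize_product(ko_model, spec, product, extra_bounds=pins)
        if not after.optimal:
            raise FBAError(f"knockout H2 maximization infeasible under {condition}")
        h_ko = after.objective_value

    if abs(h_base) <= 1e-9 and abs(h_ko) <= 1e-9:
        fold = 1.0
    elif abs(h_base) <= 1e-9:
        fold = float("inf")
    else:
        fold = h_ko / h_base

    producer = after if after is not None else baseline
    comparison = compare_fluxes(wt, producer, threshold=threshold)
    directions = _subsystem_direction(bounded, wt, producer, threshold=threshold)
    return H2StudyReport(
        condition=condition,
        knockouts=tuple(knockouts),
        substrate_minimum=substrate_min,
        baseline_h2_max=h_base,
        knockout_h2_max=h_ko,
        fold_change=fold,
        wildtype=wt,
        baseline=baseline,
        after_knockout=after,
        comparison=comparison,
        direction_table=directions,
    )
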