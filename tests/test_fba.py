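"""Tests for the LP core: FBA solving, the two optimizations, knockouts."""

import numpy as np
import pytest

from phycoflux.core import CompartmentalizedModel, Metabolite, Reaction
from phycoflux.fba import (
    FBAError,
    ScenarioSpec,
    knockout,
    maximize_product,
    minimize_substrate,
    solve_fba,
)
from phycoflux.scenarios import apply_condition

from conftest import assert_steady_state, branched_model, chain_model
from _oracles import enumerate_vertex_optimum


class TestSolveFBA:
    def test_bound_limited_chain(self, chain):
        dist = solve_fba(chain, "DM_b", sense="max")
        assert dist.objective_value == pytest.approx(10.0)
        assert_steady_state(dist, chain)

    def test_branched_network_matches_vertex_oracle(self):
        m = branched_model()
        dist = solve_fba(m, "DM_c", sense="max")
        oracle = enumerate_vertex_optimum(m, "DM_c", "max")
        assert dist.objective_value == pytest.approx(oracle, rel=1e-8)
        assert dist.objective_value == pytest.approx(4.0)  # all via GOOD branch
        assert_steady_state(dist, m)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_networks_match_oracle(self, seed):
        """Seeded random <=8-reaction networks: HiGHS vs brute-force vertices."""
        rng = np.random.default_rng(seed)
        n_mets, n_rxns = 4, 7
        mets = [Metabolite(f"m{i}_c", "cytosol") for i in range(n_mets)] + [
            Metabolite("s_e", "extracellular", is_boundary=True)
        ]
        rxns = [
            Reaction("EX_s_e", {"s_e": -1.0}, reversible=True,
                     lower_bound=-5.0, upper_bound=0.0, kind="exchange"),
            Reaction("IN", {"s_e": -1.0, "m0_c": 1.0}, kind="transport"),
        ]
        for j in range(n_rxns - 3):
            picks = rng.choice(n_mets, size=2, replace=False)
            coeffs = rng.integers(1, 3, size=2)
            stoich = {f"m{picks[0]}_c": -float(coeffs[0]),
                      f"m{picks[1]}_c": float(coeffs[1])}
            rev = bool(rng.integers(0, 2))
            rxns.append(Reaction(f"R{j}", stoich, reversible=rev,
                                 lower_bound=-3.0 if rev else 0.0,
                                 upper_bound=3.0))
        sink = int(rng.integers(0, n_mets))
        rxns.append(Reaction("DM", {f"m{sink}_c": -1.0}, kind="biomass_drain",
                             upper_bound=6.0))
        m = CompartmentalizedModel(mets, rxns)
        dist = solve_fba(m, "DM", sense="max")
        oracle = enumerate_vertex_optimum(m, "DM", "max")
        assert dist.status == "optimal" and oracle is not None
        assert dist.objective_value == pytest.approx(oracle, rel=1e-8, abs=1e-8)
        assert_steady_state(dist, m)

    def test_closed_system_zero_optimum(self, chain):
        closed = chain.copy()
        closed.set_bounds("EX_a_e", 0.0, 0.0)
        dist = solve_fba(closed, "AB", sense="max")
        assert dist.optimal and dist.objective_value == pytest.approx(0.0)

    def test_unknown_objective_raises(self, chain):
        with pytest.raises(FBAError, match="unknown objective"):
            solve_fba(chain, "NOPE")

    def test_empty_model_raises(self):
        with pytest.raises(FBAError, match="no reactions"):
            solve_fba(CompartmentalizedModel(), "X")

    def test_infeasible_is_status_not_exception(self, chain):
        work = chain.copy()
        work.set_bounds("EX_a_e", 0.0, 0.0)
        work.set_bounds("DM_b", 1.0, 1.0)  # demand flux with closed supply
        dist = solve_fba(work, "DM_b", sense="max")
        assert dist.status == "infeasible"

    def test_unbounded_is_status(self):
        m = CompartmentalizedModel(
            [Metabolite("a_c", "cytosol"), Metabolite("b_c", "cytosol")],
            [
                Reaction("F", {"a_c": -1.0, "b_c": 1.0}, upper_bound=np.inf),
                Reaction("B", {"b_c": -1.0, "a_c": 1.0}, upper_bound=np.inf),
            ],
        )
        dist = solve_fba(m, "F", sense="max")
        assert dist.status == "unbounded"

    def test_parsimonious_reduces_total_flux(self, core_model):
        bounded, spec = apply_condition(core_model, "autotrophic")
        bounded.set_bounds("BIOMASS", 0.059, 0.059)
        plain = solve_fba(bounded, "EX_photon_e", "max", parsimonious=False)
        pfba = solve_fba(bounded, "EX_photon_e", "max", parsimonious=True)
        assert pfba.objective_value == pytest.approx(plain.objective_value)
        assert sum(abs(v) for v in pfba.fluxes.values()) <= sum(
            abs(v) for v in plain.fluxes.values()
        ) + 1e-6
        assert_steady_state(pfba, bounded)


class TestMinimizeSubstrate:
    def test_autotrophic_positive_photon_demand(self, core_model):
        bounded, spec = apply_condition(core_model, "autotrophic")
        dist = minimize_substrate(bounded, spec)
        assert dist.optimal
        assert -dist.fluxes["EX_photon_e"] > 0.0
        assert dist.fluxes["BIOMASS"] == pytest.approx(0.059)
        assert_steady_state(dist, bounded)

    def test_zero_growth_needs_only_maintenance(self, core_model):
        bounded, spec = apply_condition(core_model, "autotrophic")
        spec0 = ScenarioSpec(
            condition=spec.condition,
            bound_overrides=spec.bound_overrides,
            fixed_growth_rate=0.0,
            objective_1=spec.objective_1,
            substrate_exchange=spec.substrate_exchange,
        )
        dist = minimize_substrate(bounded, spec0)
        # only the non-growth maintenance demand remains
        no_ngam = dict(spec.bound_overrides)
        no_ngam["ATPM_c"] = (0.0, 1000.0)
        spec00 = ScenarioSpec(
            condition=spec.condition, bound_overrides=no_ngam,
            fixed_growth_rate=0.0, objective_1=spec.objective_1,
            substrate_exchange=spec.substrate_exchange,
        )
        dist0 = minimize_substrate(bounded, spec00)
        assert dist0.optimal and -dist0.fluxes["EX_photon_e"] == pytest.approx(0.0)
        assert dist.optimal and -dist.fluxes["EX_photon_e"] > 0.0

    def test_substrate_scales_linearly_with_growth(self, core_model):
        bounded, spec = apply_condition(core_model, "autotrophic")
        # strip the fixed maintenance demand so the problem is homogeneous
        overrides = dict(spec.bound_overrides)
        overrides["ATPM_c"] = (0.0, 1000.0)

        def at(rate):
            s = ScenarioSpec(
                condition=spec.condition, bound_overrides=overrides,
                fixed_growth_rate=rate, objective_1=spec.objective_1,
                substrate_exchange=spec.substrate_exchange,
            )
            d = minimize_substrate(bounded, s)
            assert d.optimal
            return -d.fluxes["EX_photon_e"]

        assert at(0.06) == pytest.approx(2 * at(0.03), rel=1e-6)


class TestMaximizeProduct:
    def test_product_bounded_to_zero_gives_zero(self, core_model):
        bounded, spec = apply_condition(core_model, "mixotrophic")
        dist = maximize_product(
            bounded, spec, "EX_h2_e", extra_bounds={"EX_h2_e": (0.0, 0.0)}
        )
        assert dist.optimal and dist.objective_value == pytest.approx(0.0)

    def test_h2_nondecreasing_in_acetate_supply(self, core_model):
        """LP optimum is monotone when a bound is relaxed."""
        bounded, spec = apply_condition(core_model, "heterotrophic")
        values = []
        for supply in (1.2, 1.5, 1.8):
            dist = maximize_product(
                bounded, spec, "EX_h2_e",
                extra_bounds={"EX_ac_e": (-supply, 0.0)},
            )
            assert dist.optimal
            assert_steady_state(dist, bounded)
            values.append(dist.objective_value)
        assert values[0] <= values[1] + 1e-9 <= values[2] + 2e-9

    def test_dark_h2_runs_through_pfr(self, core_model):
        from phycoflux.scenarios import DARK_SUBSTRATE_ALLOWANCE

        bounded, spec = apply_condition(core_model, "heterotrophic")
        wt = minimize_substrate(bounded, spec)
        supply = -wt.fluxes["EX_ac_e"] * DARK_SUBSTRATE_ALLOWANCE
        dist = maximize_product(
            bounded, spec, "EX_h2_e",
            extra_bounds={"EX_ac_e": (-supply, -supply)},
        )
        assert dist.optimal and dist.objective_value > 1e-4
        assert dist.fluxes["PFR1_p"] > 1e-6
        assert dist.fluxes["HYDA_p"] > 1e-6


class TestKnockout:
    def test_bounds_zeroed_and_recorded(self, core_model):
        ko = knockout(core_model, ["CEF_p"])
        assert ko.reactions["CEF_p"].lower_bound == 0.0
        assert ko.reactions["CEF_p"].upper_bound == 0.0
        assert ko.knockout_record["CEF_p"] == (0.0, 1000.0)
        # original untouched
        assert core_model.reactions["CEF_p"].upper_bound == 1000.0

    def test_knockout_of_zero_bounded_reaction_is_idempotent(self, core_model):
        once = knockout(core_model, ["CEF_p"])
        twice = knockout(once, ["CEF_p"])
        assert twice.reactions["CEF_p"].lower_bound == 0.0
        assert twice.reactions["CEF_p"].upper_bound == 0.0

    def test_unknown_id_raises(self, core_model):
        with pytest.raises(FBAError, match="unknown"):
            knockout(core_model, ["NOPE"])

    def test_sole_producer_knockout_infeasible_at_fixed_growth(self, core_model):
        bounded, spec = apply_condition(core_model, "autotrophic")
        ko = knockout(bounded, ["STARCHS_p"])  # sole starch producer
        dist = minimize_substrate(ko, spec)
        assert dist.status == "infeasible"

    def test_zero_flux_knockout_leaves_optimum_unchanged(self, core_model):
        """Removing a reaction idle in the reference optimum is neutral."""
        bounded, spec = apply_condition(core_model, "autotrophic")
        ref = minimize_substrate(bounded, spec)
        idle = next(
            rid for rid in ("LDH_c", "PFL_c")
            if abs(ref.fluxes[rid]) < 1e-9
        )
        ko = knockout(bounded, [idle])
        dist = minimize_substrate(ko, spec)
        assert dist.objective_value == pytest.approx(
            ref.objective_value, abs=1e-6
        )
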