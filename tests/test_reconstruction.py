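"""Tests for the curation pipeline (synonyms, polymers, compartments,
transporters)."""

import pytest

from phycoflux.core import CompartmentalizedModel, Metabolite, Reaction
from phycoflux.reconstruction import (
    CurationError,
    EvidenceRecord,
    SynonymTable,
    TransporterEntry,
    add_exchanges,
    add_transporters,
    assign_compartments,
    expand_polymer_reactions,
    merge_duplicate_compounds,
)

from _oracles import per_species_net_coefficients


def _mets(*ids):
    return [Metabolite(i, "cytosol") for i in ids]


class TestSynonymMerge:
    def test_stereoisomer_duplicates_collapse_with_or_joined_gpr(self):
        # two reactions identical except for the sugar label
        m = CompartmentalizedModel(
            _mets("dglc_c", "adglc_c", "g6p_c"),
            [
                Reaction("HEX1", {"dglc_c": -1.0, "g6p_c": 1.0},
                         gene_association="hxk1"),
                Reaction("HEX2", {"adglc_c": -1.0, "g6p_c": 1.0},
                         gene_association="glk1"),
            ],
        )
        merged, report = merge_duplicate_compounds(
            m, SynonymTable({"adglc_c": "dglc_c"})
        )
        assert len(merged.reactions) == 1
        (rxn,) = merged.reactions.values()
        assert rxn.gene_association == "hxk1 or glk1"
        assert ("adglc_c", "dglc_c") in report["species_merged"]
        assert report["reactions_merged"] == [("HEX1", "HEX2")]

    def test_empty_synonym_table_is_identity(self, core_model):
        merged, report = merge_duplicate_compounds(core_model, SynonymTable({}))
        assert merged.reaction_ids == core_model.reaction_ids
        assert merged.metabolite_ids == core_model.metabolite_ids
        assert report["species_merged"] == []

    def test_coefficients_sum_and_cancel(self):
        # a reaction consuming one synonym and producing the other nets out
        m = CompartmentalizedModel(
            _mets("x1_c", "x2_c", "y_c", "z_c"),
            [Reaction("R", {"x1_c": -2.0, "x2_c": 1.0, "y_c": -1.0, "z_c": 1.0},
                      reversible=True)],
        )
        syn = {"x2_c": "x1_c"}
        merged, _ = merge_duplicate_compounds(m, SynonymTable(syn))
        expected = per_species_net_coefficients(
            {"x1_c": -2.0, "x2_c": 1.0, "y_c": -1.0, "z_c": 1.0}, syn
        )
        assert merged.reactions["R"].stoichiometry == pytest.approx(expected)

    def test_full_cancellation_drops_species(self):
        m = CompartmentalizedModel(
            _mets("x1_c", "x2_c", "y_c", "z_c"),
            [Reaction("R", {"x1_c": -1.0, "x2_c": 1.0, "y_c": -1.0, "z_c": 1.0})],
        )
        merged, _ = merge_duplicate_compounds(m, SynonymTable({"x2_c": "x1_c"}))
        assert "x1_c" not in merged.reactions["R"].stoichiometry

    def test_synonym_cycle_rejected(self):
        with pytest.raises(CurationError, match="cycle"):
            SynonymTable({"a": "b", "b": "a"})

    def test_chain_resolution_idempotent(self):
        t = SynonymTable({"a": "b", "b": "c"})
        assert t.resolve("a") == "c"
        assert t.resolve(t.resolve("a")) == t.resolve("a")


class TestPolymerExpansion:
    def test_starch_elongation_rewritten_to_monomer_drain(self):
        m = CompartmentalizedModel(
            _mets("starch(n)_c", "starch(n+1)_c", "adpglc_c", "adp_c"),
            [Reaction("SS", {"starch(n)_c": -1.0, "adpglc_c": -1.0,
                             "starch(n+1)_c": 1.0, "adp_c": 1.0})],
        )
        out = expand_polymer_reactions(m, {"starch": "starch_unit_c"})
        assert out.reactions["SS"].stoichiometry == {
            "adpglc_c": -1.0, "starch_unit_c": 1.0, "adp_c": 1.0
        }
        assert "starch(n)_c" not in out.metabolites

    def test_no_polymers_unchanged(self, core_model):
        out = expand_polymer_reactions(core_model, {})
        assert out.reaction_ids == core_model.reaction_ids

    def test_r_group_species_rejected(self):
        m = CompartmentalizedModel(
            [Metabolite("rgroup_c", "cytosol", formula="C2H4R"),
             Metabolite("b_c", "cytosol")],
            [Reaction("R1", {"rgroup_c": -1.0, "b_c": 1.0})],
        )
        with pytest.raises(CurationError, match="R-group"):
            expand_polymer_reactions(m, {})

    def test_polymer_without_mapping_rejected(self):
        m = CompartmentalizedModel(
            _mets("dna(n)_c", "dna(n+1)_c", "datp_c"),
            [Reaction("POL", {"dna(n)_c": -1.0, "datp_c": -1.0,
                              "dna(n+1)_c": 1.0})],
        )
        with pytest.raises(CurationError, match="dna"):
            expand_polymer_reactions(m, {})


class TestCompartmentAssignment:
    RAW = Reaction("PK", {"pep": -1.0, "adp": -1.0, "pyr": 1.0, "atp": 1.0})

    def test_literature_beats_homolog(self):
        placed = assign_compartments(
            [self.RAW],
            [
                EvidenceRecord("PK", "mitochondrion", "literature"),
                EvidenceRecord("PK", "microbody", "homolog"),
            ],
        )
        assert [r.id for r in placed] == ["PK_m"]
        assert placed[0].compartment_evidence == "literature"
        assert set(placed[0].stoichiometry) == {"pep_m", "adp_m", "pyr_m", "atp_m"}

    def test_no_evidence_defaults_to_cytosol(self):
        placed = assign_compartments([self.RAW], [])
        assert [r.id for r in placed] == ["PK_c"]
        assert placed[0].compartment_evidence == "default_cytosol"

    def test_two_literature_claims_duplicate_reaction(self):
        placed = assign_compartments(
            [self.RAW],
            [
                EvidenceRecord("PK", "plastid", "literature"),
                EvidenceRecord("PK", "cytosol", "literature"),
            ],
        )
        assert sorted(r.id for r in placed) == ["PK_c", "PK_p"]
        # one copy per distinct literature claim
        assert len(placed) == 2

    def test_assignment_single_compartment_per_copy(self, core_model):
        for rid in core_model.reaction_ids:
            rxn = core_model.reactions[rid]
            comps = core_model.reaction_compartments(rxn)
            if rxn.kind == "transport":
                assert len(comps) == 2
            else:
                assert len(comps) <= 2  # biomass spans drains, enzymes stay in 1
            if rxn.kind == "enzymatic":
                assert len(comps) == 1


class TestTransporters:
    def _base(self):
        return CompartmentalizedModel(
            [
                Metabolite("glyclt_c", "cytosol"),
                Metabolite("succ_x", "microbody"),
                Metabolite("succ_m", "mitochondrion"),
            ]
        )

    def test_intercellular_and_interorganelle_counted_separately(self):
        model, counts = add_transporters(
            self._base(),
            [
                TransporterEntry("glyclt", "cytosol", "extracellular",
                                 reversible=False),
                TransporterEntry("succ", "microbody", "mitochondrion",
                                 reversible=False),
            ],
        )
        assert counts == {"intercellular": 1, "interorganelle": 1}
        assert "T_glyclt_ce" in model.reactions
        assert model.reactions["T_succ_xm"].kind == "transport"

    def test_missing_species_rejected_without_creation(self):
        with pytest.raises(CurationError, match="absent"):
            add_transporters(
                self._base(),
                [TransporterEntry("unknowium", "cytosol", "plastid")],
                create_missing=False,
            )

    def test_empty_table_identity(self, core_model):
        model, counts = add_transporters(core_model, [])
        assert model.reaction_ids == core_model.reaction_ids
        assert counts == {"intercellular": 0, "interorganelle": 0}

    def test_antiport_cotransport_stoichiometry(self):
        base = CompartmentalizedModel(
            [Metabolite("atp_c", "cytosol"), Metabolite("atp_m", "mitochondrion"),
             Metabolite("adp_c", "cytosol"), Metabolite("adp_m", "mitochondrion")]
        )
        model, _ = add_transporters(
            base, [TransporterEntry("atp", "mitochondrion", "cytosol",
                                    cotransport="adp")]
        )
        assert model.reactions["T_atp_mc"].stoichiometry == {
            "atp_m": -1.0, "atp_c": 1.0, "adp_c": -1.0, "adp_m": 1.0
        }


class TestPipelineProperties:
    def test_pipeline_idempotence(self, core_model):
        """merge -> expand -> add_transporters applied twice equals once."""
        from phycoflux.fixtures import fixture_hash

        syn = SynonymTable({})
        once, _ = merge_duplicate_compounds(core_model, syn)
        once = expand_polymer_reactions(once, {})
        once, _ = add_transporters(once, [])
        twice, _ = merge_duplicate_compounds(once, syn)
        twice = expand_polymer_reactions(twice, {})
        twice, _ = add_transporters(twice, [])
        assert fixture_hash(once) == fixture_hash(twice)

    def test_merge_preserves_elemental_balance_of_untouched_reactions(
        self, core_model
    ):
        from phycoflux.core import elemental_balance_audit
        from phycoflux.fixtures import formula_table_for

        merged, _ = merge_duplicate_compounds(core_model, SynonymTable({}))
        table = formula_table_for(merged)
        for rid in merged.reaction_ids:
            rep = elemental_balance_audit(merged.reactions[rid], table)
            assert rep.status in ("balanced", "exempt")


class TestExchanges:
    def test_exchange_bounds_and_convention(self):
        model = add_exchanges(CompartmentalizedModel(), {"co2": (-5.0, 1000.0)})
        ex = model.reactions["EX_co2_e"]
        assert ex.kind == "exchange"
        assert ex.lower_bound == -5.0 and ex.upper_bound == 1000.0
        assert model.metabolites["co2_e"].is_boundary
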