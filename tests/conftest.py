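import pytest

from phycoflux.core import CompartmentalizedModel, Metabolite, Reaction
from phycoflux.fba import FluxDistribution
from phycoflux.fixtures import generate_core_network

#: steady-state criterion applied to every optimal distribution in the suite
STEADY_STATE_RTOL = 1e-6


def assert_steady_state(dist: FluxDistribution, model: CompartmentalizedModel):
    """max |S v| <= 1e-6 * max(1, max |v|) for every optimal solution."""
    assert dist.status == "optimal"
    scale = max(1.0, max((abs(v) for v in dist.fluxes.values()), default=0.0))
    assert dist.residual(model) <= STEADY_STATE_RTOL * scale


@pytest.fixture(scope="session")
def core_model():
    """The canonical synthetic algal core network (immutable: copy to edit)."""
    return generate_core_network()


def chain_model(uptake_cap: float = 10.0) -> CompartmentalizedModel:
    """EX_a -> a_e -> a_c -> b_c -> drain, uptake capped."""
    mets = [
        Metabolite("a_e", "extracellular", is_boundary=True),
        Metabolite("a_c", "cytosol"),
        Metabolite("b_c", "cytosol"),
    ]
    rxns = [
        Reaction("EX_a_e", {"a_e": -1.0}, reversible=True,
                 lower_bound=-uptake_cap, upper_bound=0.0, kind="exchange"),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, kind="transport"),
        Reaction("AB", {"a_c": -1.0, "b_c": 1.0}),
        Reaction("DM_b", {"b_c": -1.0}, kind="biomass_drain"),
    ]
    return CompartmentalizedModel(mets, rxns)


@pytest.fixture
def chain():
    return chain_model()


def branched_model() -> CompartmentalizedModel:
    """Two routes from a to c with different yields: the LP must pick the
    higher-yield branch (1 c per a) over the lossy one (0.5 c per a)."""
    mets = [
        Metabolite("a_e", "extracellular", is_boundary=True),
        Metabolite("a_c", "cytosol"),
        Metabolite("c_c", "cytosol"),
    ]
    rxns = [
        Reaction("EX_a_e", {"a_e": -1.0}, reversible=True,
                 lower_bound=-4.0, upper_bound=0.0, kind="exchange"),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, kind="transport"),
        Reaction("GOOD", {"a_c": -1.0, "c_c": 1.0}),
        Reaction("LOSSY", {"a_c": -2.0, "c_c": 1.0}),
        Reaction("DM_c", {"c_c": -1.0}, kind="biomass_drain"),
    ]
    return CompartmentalizedModel(mets, rxns)
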