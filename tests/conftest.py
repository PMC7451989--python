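import numpy as np
import pytest

from fluxcouple import GPR, Metabolite, MetabolicModel, Reaction, ReactionKind


@pytest.fixture
def chain_model():
    """glc_e -> g6p -> pyr (2x) -> biomass; textbook linear chain."""
    mets = [
        Metabolite("glc_e", formula="C6H12O6", compartment="e"),
        Metabolite("g6p_c", formula="C6H12O6", compartment="c"),
        Metabolite("pyr_c", formula="C3H6O3", compartment="c"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1.0}, -10.0, 1000.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("GLCT", {"glc_e": -1.0, "g6p_c": 1.0}, 0.0, 1000.0,
                 gpr=GPR.parse("gT"), kind=ReactionKind.TRANSPORT),
        Reaction("GLY", {"g6p_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0,
                 gpr=GPR.parse("gG1 and gG2")),
        Reaction("BIOMASS", {"pyr_c": -1.0}, 0.0, 1000.0,
                 kind=ReactionKind.BIOMASS),
    ]
    return MetabolicModel(
        id="chain", metabolites=mets, reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture
def fermentation_model():
    """Glucose to ethanol + CO2 with an isozyme pair and a biomass drain.

    glc -> 2 pyr; pyr -> eth + co2 (two isozymes); pyr -> biomass.
    Balanced formulas so the balance checker has something real to verify.
    """
    mets = [
        Metabolite("glc_e", formula="C6H12O6", compartment="e"),
        Metabolite("glc_c", formula="C6H12O6", compartment="c"),
        Metabolite("pyr_c", formula="C3H6O3", compartment="c"),
        Metabolite("eth_c", formula="C2H6O", compartment="c"),
        Metabolite("co2_c", formula="CO2", compartment="c"),
        Metabolite("eth_e", formula="C2H6O", compartment="e"),
        Metabolite("co2_e", formula="CO2", compartment="e"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1.0}, -10.0, 1000.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("GLCT", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0,
                 gpr=GPR.parse("glf"), kind=ReactionKind.TRANSPORT),
        Reaction("GLY", {"glc_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0,
                 gpr=GPR.parse("eda and edd")),
        Reaction("FERM", {"pyr_c": -1.0, "eth_c": 1.0, "co2_c": 1.0},
                 0.0, 1000.0, gpr=GPR.parse("adhA or adhB")),
        Reaction("ETHT", {"eth_c": -1.0, "eth_e": 1.0}, 0.0, 1000.0,
                 kind=ReactionKind.TRANSPORT),
        Reaction("CO2T", {"co2_c": -1.0, "co2_e": 1.0}, 0.0, 1000.0,
                 kind=ReactionKind.TRANSPORT),
        Reaction("EX_eth_e", {"eth_e": -1.0}, 0.0, 1000.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("EX_co2_e", {"co2_e": -1.0}, 0.0, 1000.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("BIOMASS", {"pyr_c": -1.0}, 0.0, 1000.0,
                 kind=ReactionKind.BIOMASS),
    ]
    return MetabolicModel(
        id="ferm", metabolites=mets, reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
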