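import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from limflux import MetabolicModel, Metabolite, Reaction


@pytest.fixture
def toy_chain():
    """Linear chain A_b -> A -> B -> B_b with boundary ends.

    At steady state all three fluxes are forced equal, so fixing any one
    determines the whole flux vector.
    """
    mets = [
        Metabolite("M_A_b", compartment="e", is_boundary=True),
        Metabolite("M_A", compartment="c"),
        Metabolite("M_B", compartment="c"),
        Metabolite("M_B_b", compartment="e", is_boundary=True),
    ]
    rxns = [
        Reaction("R1", {"M_A_b": -1, "M_A": 1}, reversible=True,
                 gene_association="g1 or g4"),
        Reaction("R2", {"M_A": -1, "M_B": 1}, reversible=True,
                 gene_association="(g1 and g2) or g3"),
        Reaction("R3", {"M_B": -1, "M_B_b": 1}, reversible=True),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          annotations={"chain": ["R1", "R2", "R3"]},
                          id="toy_chain")


@pytest.fixture
def branched_toy():
    """Source -> M -> (two parallel irreversible routes) -> P -> sink.

    With the source fixed to 1, the split between the two branches is a
    one-parameter family: each branch can carry anything in [0, 1].
    """
    mets = [
        Metabolite("M_S_b", compartment="e", is_boundary=True),
        Metabolite("M_M", compartment="c"),
        Metabolite("M_P", compartment="c"),
        Metabolite("M_P_b", compartment="e", is_boundary=True),
    ]
    rxns = [
        Reaction("R_in", {"M_S_b": -1, "M_M": 1}, reversible=True),
        Reaction("R_a", {"M_M": -1, "M_P": 1}, reversible=False,
                 gene_association="ga"),
        Reaction("R_b", {"M_M": -1, "M_P": 1}, reversible=False,
                 gene_association="gb"),
        Reaction("R_out", {"M_P": -1, "M_P_b": 1}, reversible=False),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, id="branched_toy")
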