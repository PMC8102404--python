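import json

import pytest

from fluxlip.synthetic_data import branched_toy_model, box_model, toy_chain_model

TOY_JSON = {
    "id": "toy3",
    "metabolites": [
        {"id": "A", "name": "A", "compartment": "c"},
        {"id": "B", "name": "B", "compartment": "c"},
    ],
    "reactions": [
        {
            "id": "EX_A",
            "metabolites": {"A": -1.0},
            "lower_bound": -10.0,
            "upper_bound": 0.0,
            "subsystem": "Transport, extracellular",
            "gene_reaction_rule": "",
        },
        {
            "id": "R1",
            "metabolites": {"A": -1.0, "B": 1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "subsystem": "Fatty acid oxidation",
            "gene_reaction_rule": "g1 and g2",
        },
        {
            "id": "EX_B",
            "metabolites": {"B": -1.0},
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "subsystem": "Transport, extracellular",
            "gene_reaction_rule": "",
            "objective_coefficient": 1.0,
        },
    ],
    "genes": [{"id": "g1", "name": "g1"}, {"id": "g2", "name": "g2"}],
}


@pytest.fixture
def toy_json_path(tmp_path):
    p = tmp_path / "toy3.json"
    p.write_text(json.dumps(TOY_JSON))
    return p


@pytest.fixture
def toy_chain():
    return toy_chain_model()


@pytest.fixture
def branched_toy():
    return branched_toy_model()


@pytest.fixture
def box2():
    return box_model([(0.0, 4.0), (0.0, 3.0)])
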