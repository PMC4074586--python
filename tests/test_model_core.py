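"""Model container, reaction classification, media, and JSON round-trips."""

import json

import numpy as np
import pytest

from fluxvar import (
    MediumSpec,
    ModelError,
    ReactionClass,
    apply_medium,
    build_model,
    classify_reactions,
    make_toy,
    read_model,
    write_bigg_json,
)


def _inline_toy1_json(tmp_path, **overrides):
    doc = {
        "id": "toy1",
        "metabolites": [{"id": "A"}, {"id": "B"}],
        "reactions": [
            {"id": "EX_A", "metabolites": {"A": -1.0}, "lower_bound": -10.0,
             "upper_bound": 0.0, "objective_coefficient": 0.0},
            {"id": "R1", "metabolites": {"A": -1.0, "B": 1.0}, "lower_bound": 0.0,
             "upper_bound": 50.0, "objective_coefficient": 0.0},
            {"id": "GRO", "metabolites": {"B": -1.0}, "lower_bound": 0.0,
             "upper_bound": 50.0, "objective_coefficient": 1.0},
        ],
    }
    doc.update(overrides)
    path = tmp_path / "toy1.json"
    path.write_text(json.dumps(doc))
    return path


def test_read_bigg_json_assembles_model(tmp_path):
    model = read_model(_inline_toy1_json(tmp_path))
    assert model.n_reactions == 3
    assert model.n_metabolites == 2
    assert model.biomass_reaction == "GRO"
    assert model.reaction_classes["EX_A"] is ReactionClass.EXCHANGE


def test_read_rejects_inverted_bounds(tmp_path):
    path = _inline_toy1_json(tmp_path)
    doc = json.loads(path.read_text())
    doc["reactions"][1]["lower_bound"] = 60.0  # exceeds its upper bound
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelError, match="lower bound exceeds"):
        read_model(path)


def test_read_rejects_ambiguous_objective(tmp_path):
    path = _inline_toy1_json(tmp_path)
    doc = json.loads(path.read_text())
    doc["reactions"][1]["objective_coefficient"] = 1.0
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelError, match="ambiguous objective"):
        read_model(path)


def test_read_rejects_missing_objective(tmp_path):
    path = _inline_toy1_json(tmp_path)
    doc = json.loads(path.read_text())
    for r in doc["reactions"]:
        r["objective_coefficient"] = 0.0
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelError, match="no objective"):
        read_model(path)


def test_missing_file_errors():
    with pytest.raises(ModelError, match="not found"):
        read_model("does_not_exist.json")


@pytest.mark.parametrize(
    "preset,expected",
    [
        ("chain", {"EX_A": "exchange", "R1": "internal", "GRO": "growth"}),
        (
            "branched",
            {"EX_A": "exchange", "R1": "internal", "R2": "internal",
             "R3": "internal", "R4": "internal", "GRO": "growth"},
        ),
    ],
)
def test_classification_by_rule(preset, expected):
    model = make_toy(preset)
    got = {r: c.value for r, c in model.reaction_classes.items()}
    assert got == expected


def test_classification_partitions_reactions(toy3):
    classes = toy3.reaction_classes
    counts = {c: sum(1 for v in classes.values() if v is c) for c in ReactionClass}
    assert sum(counts.values()) == toy3.n_reactions
    assert counts[ReactionClass.GROWTH] == 1


def test_sink_without_biomass_role_is_exchange():
    # a demand reaction draining one metabolite, not designated biomass
    model = build_model(
        "sink",
        ["A", "B"],
        [
            ("EX_A", {"A": -1.0}, -5.0, 0.0),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
            ("GRO", {"B": -1.0}, 0.0, 10.0),
            ("DM_B", {"B": -1.0}, 0.0, 10.0),
        ],
        biomass="GRO",
    )
    assert model.reaction_classes["DM_B"] is ReactionClass.EXCHANGE


def test_classify_unknown_biomass_errors(toy1):
    with pytest.raises(ModelError):
        classify_reactions(toy1, "NOPE")


def test_apply_medium_sets_uptake_sign_convention(toy1):
    medium = MediumSpec(exchanges={"EX_A": (7.0, None)}, oxygen_exchange="EX_O2")
    conditioned = apply_medium(toy1, medium)
    j = conditioned.index("EX_A")
    assert conditioned.lower_bounds[j] == -7.0  # uptake 7 => lb -7 (BiGG sign)
    assert conditioned.upper_bounds[j] > 0  # secretion left unbounded
    # original untouched
    assert toy1.lower_bounds[toy1.index("EX_A")] == -10.0


def test_apply_medium_idempotent(toy2):
    medium = MediumSpec(exchanges={"EX_A": (4.0, 2.0)}, oxygen_exchange="EX_O2")
    once = apply_medium(toy2, medium)
    twice = apply_medium(once, medium)
    assert np.array_equal(once.lower_bounds, twice.lower_bounds)
    assert np.array_equal(once.upper_bounds, twice.upper_bounds)


def test_apply_medium_closes_unlisted_exchanges(toy3):
    medium = MediumSpec(exchanges={"EX_C": (10.0, None)}, oxygen_exchange="EX_O2")
    conditioned = apply_medium(toy3, medium)
    j = conditioned.index("EX_N")
    assert conditioned.lower_bounds[j] == 0.0  # uptake closed


def test_anaerobic_flag_closes_oxygen(toy3):
    # treat the nitrogen-like exchange as the 'oxygen' of this toy
    medium = MediumSpec(
        exchanges={"EX_C": (10.0, None), "EX_N": (20.0, None)},
        aerobic=False,
        oxygen_exchange="EX_N",
    )
    conditioned = apply_medium(toy3, medium)
    assert conditioned.lower_bounds[conditioned.index("EX_N")] == 0.0


def test_medium_rejects_internal_reaction(toy1):
    medium = MediumSpec(exchanges={"R1": (1.0, None)})
    with pytest.raises(ModelError, match="non-exchange"):
        apply_medium(toy1, medium)


def test_medium_rejects_negative_limit():
    with pytest.raises(ModelError, match="negative limit"):
        MediumSpec(exchanges={"EX_A": (-1.0, None)})


def test_medium_yaml_round_trip(tmp_path):
    medium = MediumSpec(
        exchanges={"EX_A": (10.0, None), "EX_B": (0.5, 3.0)},
        name="test-medium",
        aerobic=False,
        oxygen_exchange="EX_B",
    )
    path = tmp_path / "medium.yaml"
    medium.to_yaml(path)
    back = MediumSpec.from_yaml(path)
    assert back == medium


def test_json_round_trip_exact(tmp_path, toy3):
    path = tmp_path / "toy3.json"
    write_bigg_json(toy3, path)
    back = read_model(path)
    assert back.reaction_ids == toy3.reaction_ids
    assert back.metabolite_ids == toy3.metabolite_ids
    assert np.array_equal(back.lower_bounds, toy3.lower_bounds)
    assert np.array_equal(back.upper_bounds, toy3.upper_bounds)
    assert (back.stoichiometry != toy3.stoichiometry).nnz == 0
    assert {r: c for r, c in back.reaction_classes.items()} == {
        r: c for r, c in toy3.reaction_classes.items()
    }


def test_uptake_sign_helpers(toy1):
    assert toy1.uptake_flux("EX_A", 10.0) == -10.0
    assert toy1.uptake_rate("EX_A", -10.0) == 10.0
    with pytest.raises(ModelError):
        toy1.uptake_flux("R1", 1.0)
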