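"""The delta and sigma measures and the internal/external/growth
decomposition, on toy networks with oracle-derived golden values."""

import numpy as np
import pandas as pd
import pytest

from fluxvar import (
    EmptyAdmissibleSetError,
    FluxRanges,
    InfeasibleError,
    ReferenceState,
    build_model,
    compute_reference_ranges,
    decompose_variability,
    delta_measure,
    make_toy,
    sigma_measure,
    solve_fva,
)


def _ranges(frame_dict) -> FluxRanges:
    frame = pd.DataFrame(frame_dict, index=["minimum", "maximum"]).T
    return FluxRanges(frame)


def _reference(frame_dict) -> ReferenceState:
    ranges = _ranges(frame_dict)
    admissible = [r for r in ranges.frame.index if ranges.widths[r] > 1e-9]
    return ReferenceState(ranges=ranges, admissible=admissible, cap_excluded=[])


def test_reference_widths_branched(toy2):
    ref = compute_reference_ranges(toy2)
    assert dict(ref.widths) == pytest.approx(
        {"R1": 10.0, "R2": 10.0, "R3": 10.0, "R4": 10.0}
    )
    assert ref.admissible == ["R1", "R2", "R3", "R4"]


def test_delta_of_reference_against_itself_is_one(toy2):
    ref = compute_reference_ranges(toy2)
    assert delta_measure(ref.ranges, ref) == pytest.approx(1.0)


def test_all_closed_model_has_empty_admissible_set(toy1):
    closed = toy1.with_bounds({"EX_A": (0.0, 0.0)})
    ref = compute_reference_ranges(closed)
    assert ref.admissible == []
    with pytest.raises(EmptyAdmissibleSetError):
        delta_measure(ref.ranges, ref)


def test_delta_direct_formula_arithmetic():
    # two admissible reactions, reference widths (2, 4), query widths (1, 1)
    ref = _reference({"a": (0.0, 2.0), "b": (0.0, 4.0)})
    query = _ranges({"a": (0.5, 1.5), "b": (1.0, 2.0)})
    assert delta_measure(query, ref) == pytest.approx((1 / 2 + 1 / 4) / 2)


def test_delta_zero_when_all_query_widths_zero():
    ref = _reference({"a": (0.0, 2.0), "b": (0.0, 4.0)})
    query = _ranges({"a": (1.0, 1.0), "b": (2.0, 2.0)})
    assert delta_measure(query, ref) == pytest.approx(0.0)


def test_delta_requires_coverage_of_admissible_set():
    ref = _reference({"a": (0.0, 2.0), "b": (0.0, 4.0)})
    query = _ranges({"a": (0.0, 2.0)})
    with pytest.raises(ValueError, match="admissible"):
        delta_measure(query, ref)


def test_sigma_one_at_reference_zero_under_total_fixing(toy2):
    ref = compute_reference_ranges(toy2)
    assert sigma_measure(ref.ranges, ref) == pytest.approx(1.0)
    fixed = solve_fva(
        toy2,
        reactions=ref.admissible,
        fixes={"EX_A": -10.0, "R1": 10.0, "R2": 10.0, "R3": 0.0, "R4": 0.0, "GRO": 10.0},
    )
    assert sigma_measure(fixed, ref) == pytest.approx(0.0, abs=1e-9)


def test_sigma_branched_with_growth_and_exchange_fixed(toy2):
    # internal ranges under GRO=10, EX=10: stem pinned, three branches free
    ref = compute_reference_ranges(toy2)
    ranges = solve_fva(toy2, reactions=ref.admissible, fixes={"GRO": 10.0, "EX_A": -10.0})
    assert sigma_measure(ranges, ref) == pytest.approx((40.0 - 10.0) / 40.0)


def test_decomposition_branched_golden(toy2):
    ref = compute_reference_ranges(toy2)
    comp = decompose_variability(toy2, ref, with_sigma=True)
    assert comp.delta_int == pytest.approx(0.75, abs=1e-6)
    assert comp.delta_ext == pytest.approx(0.0, abs=1e-6)
    assert comp.delta_gro == pytest.approx(0.25, abs=1e-6)
    assert comp.delta_tot == pytest.approx(1.0, abs=1e-6)
    assert comp.sigma_tot == pytest.approx(1.0, abs=1e-6)


def test_components_sum_identity_exact(toy2, toy3):
    for model, fixes in [(toy2, {}), (toy2, {"EX_A": -5.0}), (toy3, {"EX_N": -5.0})]:
        ref = compute_reference_ranges(model)
        comp = decompose_variability(model, ref, fixes=fixes)
        assert comp.delta_int + comp.delta_ext + comp.delta_gro == pytest.approx(
            comp.delta_tot, abs=1e-12
        )
        assert comp.delta_int >= 0
        assert comp.delta_ext >= -1e-9
        assert comp.delta_gro >= -1e-9


def test_delta_bounded_for_nested_conditions(toy2):
    # conditions tighter than the reference keep delta in [0, 1)
    ref = compute_reference_ranges(toy2)
    for fixes in ({"EX_A": -5.0}, {"GRO": 2.5}, {"EX_A": -7.5, "GRO": 7.5}):
        ranges = solve_fva(toy2, reactions=ref.admissible, fixes=fixes)
        d = delta_measure(ranges, ref)
        assert 0.0 <= d < 1.0


def test_delta_monotone_under_bound_tightening(toy2):
    ref = compute_reference_ranges(toy2)
    deltas = []
    for cap in (10.0, 7.0, 4.0, 1.0):
        ranges = solve_fva(
            toy2, reactions=ref.admissible, bound_overrides={"EX_A": (-cap, 0.0)}
        )
        deltas.append(delta_measure(ranges, ref))
    assert all(a >= b - 1e-9 for a, b in zip(deltas, deltas[1:]))


def test_steady_state_redundancy_fixing_ext_only(toy1, toy2):
    # when the growth reaction is the only biomass drain, fixing the
    # exchanges alone pins growth too: same delta as fixing both
    for model in (toy1, toy2):
        ref = compute_reference_ranges(model)
        vmax = 10.0
        ranges_both = solve_fva(
            model, reactions=ref.admissible, fixes={"EX_A": -10.0, "GRO": vmax}
        )
        ranges_ext = solve_fva(model, reactions=ref.admissible, fixes={"EX_A": -10.0})
        assert delta_measure(ranges_ext, ref) == pytest.approx(
            delta_measure(ranges_both, ref), abs=1e-9
        )


def test_degenerate_vertex_invariance_of_sums(toy2):
    """Permuting the model's reaction order can change which optimal
    exchange vertex the solver returns; delta_int and delta_ext may move
    individually but delta_int+ext and delta_gro must not."""
    ref = compute_reference_ranges(toy2)
    comp = decompose_variability(toy2, ref)

    order = [4, 3, 2, 1, 0, 5]  # reversed internals, biomass last
    reactions = []
    for k in order:
        rid = toy2.reaction_ids[k]
        col = toy2.stoichiometry.getcol(k)
        stoich = {toy2.metabolite_ids[i]: float(v) for i, v in zip(col.indices, col.data)}
        reactions.append((rid, stoich, toy2.lower_bounds[k], toy2.upper_bounds[k]))
    permuted = build_model("toy2_perm", toy2.metabolite_ids, reactions, biomass="GRO")
    ref_p = compute_reference_ranges(permuted)
    comp_p = decompose_variability(permuted, ref_p)

    assert comp.delta_int + comp.delta_ext == pytest.approx(
        comp_p.delta_int + comp_p.delta_ext, abs=1e-6
    )
    assert comp.delta_gro == pytest.approx(comp_p.delta_gro, abs=1e-6)


def test_decompose_condition_exchange_stays_fixed(toy3):
    # the scanned/fixed exchange belongs to the condition: delta_tot < 1
    ref = compute_reference_ranges(toy3)
    comp = decompose_variability(toy3, ref, fixes={"EX_N": -5.0})
    assert comp.delta_tot < 1.0
    assert comp.condition["fixes"] == {"EX_N": -5.0}


def test_decompose_infeasible_condition_raises(toy1):
    ref = compute_reference_ranges(toy1)
    with pytest.raises(InfeasibleError):
        decompose_variability(
            toy1, ref, fixes={"GRO": 5.0}, bound_overrides={"EX_A": (0.0, 0.0)}
        )


def test_cap_limited_reactions_excluded_from_admissible():
    # a free internal loop pair spans the artificial cap: its reference
    # range measures the cap, not the medium, and is excluded by default
    model = build_model(
        "loopy",
        ["A", "B", "C"],
        [
            ("EX_A", {"A": -1.0}, -10.0, 0.0),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("L1", {"B": -1.0, "C": 1.0}, -1000.0, 1000.0),
            ("L2", {"C": -1.0, "B": 1.0}, -1000.0, 1000.0),
            ("GRO", {"B": -1.0}, 0.0, 1000.0),
        ],
        biomass="GRO",
    )
    ref = compute_reference_ranges(model)
    assert set(ref.cap_excluded) == {"L1", "L2"}
    assert ref.admissible == ["R1"]
    ref_incl = compute_reference_ranges(model, include_cap_limited=True)
    assert set(ref_incl.admissible) == {"R1", "L1", "L2"}
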