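import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coroflow import (
    FlowBC,
    OcclusionPattern,
    SplitTable,
    flows_from_splits,
    mass_balance_residual,
    reynolds_number,
    segment_resistance,
    solve_network,
)
from coroflow.flow import FlowError
from coroflow.geometry import VesselSegment

from conftest import series_parallel_flows

ALL_OUTLETS = tuple(f"O{k}" for k in range(1, 9))


def seg(radius, length):
    return VesselSegment(label="X", generation=1, radius=radius, length=length, outlet_id="O1")


class TestSegmentResistance:
    def test_hagen_poiseuille_value(self, water):
        # 8 mu L / (pi r^4) for the default root segment
        assert segment_resistance(seg(0.5e-3, 2.5e-3), water) == pytest.approx(
            1.0186e8, rel=1e-4
        )

    def test_linear_in_length_and_quartic_in_radius(self, water):
        base = segment_resistance(seg(0.5e-3, 2.5e-3), water)
        assert segment_resistance(seg(0.5e-3, 5.0e-3), water) == pytest.approx(2 * base)
        assert segment_resistance(seg(0.25e-3, 2.5e-3), water) == pytest.approx(16 * base)


class TestReynolds:
    def test_inlet_value_for_default_conditions(self, default_tree, water):
        root = default_tree.root
        flow = 0.012 * math.pi * root.radius**2
        assert reynolds_number(root, flow, water) == pytest.approx(12.0, rel=1e-12)

    def test_zero_flow_and_linearity(self, default_tree, water):
        root = default_tree.root
        assert reynolds_number(root, 0.0, water) == 0.0
        assert reynolds_number(root, 2e-9, water) == pytest.approx(
            2 * reynolds_number(root, 1e-9, water)
        )


class TestSolveNetwork:
    def test_symmetric_tree_equal_splits(self, default_tree, water):
        sol = solve_network(default_tree, water)
        for frac in sol.outlet_fractions(default_tree).values():
            assert frac == pytest.approx(0.125, abs=1e-12)

    def test_single_open_outlet_takes_all_flow(self, default_tree, water):
        occ = OcclusionPattern(set(ALL_OUTLETS) - {"O8"})
        sol = solve_network(default_tree, water, occlusion=occ)
        fr = sol.outlet_fractions(default_tree)
        assert fr["O8"] == pytest.approx(1.0, abs=1e-10)
        assert all(fr[o] == 0.0 for o in ALL_OUTLETS if o != "O8")

    def test_occluded_terminals_have_zero_flow(self, default_tree, water):
        sol = solve_network(default_tree, water, occlusion=OcclusionPattern({"O3"}))
        assert sol.segment_flow[default_tree.segment_for_outlet("O3").label] == 0.0

    def test_all_occluded_is_infeasible(self, default_tree, water):
        with pytest.raises(FlowError):
            solve_network(default_tree, water, occlusion=OcclusionPattern(ALL_OUTLETS))

    def test_junction_conservation(self, default_tree, water):
        sol = solve_network(default_tree, water, occlusion=OcclusionPattern({"O1", "O5"}))
        for s in default_tree:
            if s.child_labels:
                child_sum = sum(sol.segment_flow[c] for c in s.child_labels)
                assert child_sum == pytest.approx(sol.segment_flow[s.label], rel=1e-10)

    def test_matches_series_parallel_oracle_single_occlusion(self, default_tree, water):
        occ = {"O3"}
        sol = solve_network(default_tree, water, occlusion=OcclusionPattern(occ))
        oracle = series_parallel_flows(default_tree, water, sol.inlet_flow, occ)
        for label, q in oracle.items():
            assert sol.segment_flow[label] == pytest.approx(q, rel=1e-10, abs=1e-22)

    def test_mirror_symmetry(self, default_tree, water):
        """Mirroring the occlusion pattern (Ok <-> O(9-k)) mirrors the flows."""
        occ = {"O1", "O2", "O6"}
        mirror = {f"O{9 - int(o[1:])}" for o in occ}
        fr = solve_network(default_tree, water, occlusion=OcclusionPattern(occ)).outlet_fractions(
            default_tree
        )
        fr_m = solve_network(
            default_tree, water, occlusion=OcclusionPattern(mirror)
        ).outlet_fractions(default_tree)
        for k in range(1, 9):
            assert fr[f"O{k}"] == pytest.approx(fr_m[f"O{9 - k}"], rel=1e-10, abs=1e-15)

    def test_occluding_more_never_decreases_open_outlet_flow(self, default_tree, water):
        base = solve_network(
            default_tree, water, occlusion=OcclusionPattern({"O1"})
        ).outlet_fractions(default_tree)
        more = solve_network(
            default_tree, water, occlusion=OcclusionPattern({"O1", "O4", "O7"})
        ).outlet_fractions(default_tree)
        for o in ALL_OUTLETS:
            if o not in {"O1", "O4", "O7"}:
                assert more[o] >= base[o] - 1e-12

    def test_velocity_and_flowrate_modes(self, default_tree, water):
        sol_v = solve_network(default_tree, water, bc=FlowBC(inlet_mode="velocity"))
        assert sol_v.inlet_flow == pytest.approx(0.012 * math.pi * (0.5e-3) ** 2)
        sol_q = solve_network(
            default_tree, water, bc=FlowBC(inlet_mode="flowrate", inlet_flowrate=3.25e-9)
        )
        assert sol_q.inlet_flow == pytest.approx(3.25e-9)

    @given(bits=st.integers(1, 254))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_random_patterns(self, default_tree, water, bits):
        occ = {ALL_OUTLETS[i] for i in range(8) if not (bits >> i) & 1}
        sol = solve_network(default_tree, water, occlusion=OcclusionPattern(occ))
        oracle = series_parallel_flows(default_tree, water, sol.inlet_flow, occ)
        for label, q in oracle.items():
            assert sol.segment_flow[label] == pytest.approx(q, rel=1e-10, abs=1e-22)


class TestModeEquivalence:
    @pytest.mark.parametrize("occ", [set(), {"O3"}, {"O1", "O2", "O3"}, {"O2", "O5", "O7"}])
    def test_resistance_fractions_round_trip_through_split_mode(
        self, default_tree, water, occ
    ):
        sol = solve_network(default_tree, water, occlusion=OcclusionPattern(occ))
        table = SplitTable(
            scenario_name="rt",
            flowrate=sol.outlet_fractions(default_tree),
            out_split=sol.outlet_fractions(default_tree),
            inlet_flowrate=1.0,
        )
        redo = flows_from_splits(default_tree, sol.inlet_flow, table, water)
        for label, q in sol.segment_flow.items():
            assert redo.segment_flow[label] == pytest.approx(q, rel=1e-10, abs=1e-22)


class TestFlowsFromSplits:
    def test_control_branch_fraction(self, default_tree, split_tables, water):
        sol = flows_from_splits(default_tree, 3.25e-9, split_tables["control"], water)
        assert sol.flow_fraction["C2-B2"] == pytest.approx(0.494, abs=1e-12)

    def test_case38_branch_fraction(self, default_tree, split_tables, water):
        sol = flows_from_splits(default_tree, 3.25e-9, split_tables["case_3/8"], water)
        assert sol.flow_fraction["C2-B2"] == pytest.approx(0.83, abs=1e-12)

    def test_single_outlet_path_indicator(self, default_tree, water):
        table = SplitTable(
            scenario_name="o1",
            flowrate={o: 0.0 for o in ALL_OUTLETS},
            out_split={o: (1.0 if o == "O1" else 0.0) for o in ALL_OUTLETS},
            inlet_flowrate=1.0,
        )
        sol = flows_from_splits(default_tree, 2.0e-9, table, water)
        on_path = {s.label for s in default_tree.path_to_outlet("O1")}
        for label, q in sol.segment_flow.items():
            expected = 2.0e-9 if label in on_path else 0.0
            assert q == pytest.approx(expected, abs=1e-22)

    def test_junction_conservation_exact(self, default_tree, split_tables, water):
        sol = flows_from_splits(default_tree, 3.25e-9, split_tables["case_5/8"], water)
        for s in default_tree:
            if s.child_labels:
                child_sum = sum(sol.segment_flow[c] for c in s.child_labels)
                assert child_sum == pytest.approx(sol.segment_flow[s.label], rel=1e-14)

    def test_missing_outlet_rejected(self, default_tree, water):
        table = SplitTable(
            scenario_name="bad",
            flowrate={"O1": 1.0},
            out_split={"O1": 1.0},
            inlet_flowrate=1.0,
        )
        with pytest.raises(FlowError):
            flows_from_splits(default_tree, 1e-9, table, water)

    def test_no_pressures_in_split_mode(self, default_tree, split_tables, water):
        sol = flows_from_splits(default_tree, 3.25e-9, split_tables["control"], water)
        assert sol.node_pressure is None


class TestMassBalance:
    def test_measured_control_column(self, split_tables):
        # sum of the eight printed control flowrates is 3.007 vs inlet 3.01
        assert mass_balance_residual(split_tables["control"]) == pytest.approx(
            -0.0010, abs=5e-5
        )

    def test_measured_case58_column_closes_exactly(self, split_tables):
        assert mass_balance_residual(split_tables["case_5/8"]) == pytest.approx(0.0, abs=1e-12)

    def test_consistent_synthetic_table(self):
        table = SplitTable(
            scenario_name="s",
            flowrate={f"O{k}": 0.125 for k in range(1, 9)},
            out_split={f"O{k}": 0.125 for k in range(1, 9)},
            inlet_flowrate=1.0,
        )
        assert mass_balance_residual(table) == pytest.approx(0.0, abs=1e-15)
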