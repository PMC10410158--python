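"""Steady laminar flow on the vascular tree.

Two modes are provided. *Resistance mode* treats each segment as a
Hagen-Poiseuille resistor ``R = 8 mu L / (pi r^4)`` and solves the nodal
pressure system (mass conservation at every junction, ``dP = R Q`` on
every segment, prescribed inlet flow, a common reference pressure at all
open outlets, and exact zero flow through occluded terminals). *Split
mode* bypasses the pressure problem and aggregates prescribed outlet
out-splits up the tree, mirroring the boundary-condition coupling in
which measured outlet fractions drive the model.

Flows are volumetric (m^3/s), pressures in Pa. The Reynolds numbers of
the microvascular regime are far below transition (Re ~ 12 at the 1 mm
inlet for 0.012 m/s water), so the laminar closure is safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import VascularTree, VesselSegment, downstream_outlets

__all__ = [
    "FluidProperties",
    "FlowBC",
    "OcclusionPattern",
    "FlowSolution",
    "SplitTable",
    "segment_resistance",
    "solve_network",
    "flows_from_splits",
    "reynolds_number",
    "mass_balance_residual",
]

#: 195 uL/min in m^3/s
PUMP_RATE_M3_S = 195e-9 / 60.0


class FlowError(ValueError):
    """Invalid boundary conditions or flow data."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian working fluid; defaults are water at ~20 C."""

    density: float = 1000.0  # kg/m^3
    viscosity: float = 1.0e-3  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise FlowError("density and viscosity must be positive")


WATER = FluidProperties()


@dataclass(frozen=True)
class FlowBC:
    """Inlet condition and outlet reference pressure.

    The inlet is prescribed either as a flat mean velocity over the root
    cross-section (default 0.012 m/s) or directly as a flowrate (default
    3.25e-9 m^3/s, i.e. the 195 uL/min pump setting). The two defaults
    are independent measured constants and are not mutually consistent;
    choose the mode that matches the experiment being mirrored.
    """

    inlet_mode: str = "velocity"  # "velocity" | "flowrate"
    inlet_velocity: float = 0.012  # m/s
    inlet_flowrate: float = PUMP_RATE_M3_S  # m^3/s
    outlet_pressure: float = 0.0  # Pa at all open outlets

    def __post_init__(self) -> None:
        if self.inlet_mode not in ("velocity", "flowrate"):
            raise FlowError(f"unknown inlet mode {self.inlet_mode!r}")
        active = self.inlet_velocity if self.inlet_mode == "velocity" else self.inlet_flowrate
        if active <= 0:
            raise FlowError("active inlet quantity must be positive")

    def inlet_flow(self, root: VesselSegment) -> float:
        """Prescribed inlet volumetric flow in m^3/s."""
        if self.inlet_mode == "flowrate":
            return self.inlet_flowrate
        return self.inlet_velocity * math.pi * root.radius**2


@dataclass(frozen=True)
class OcclusionPattern:
    """Set of blocked terminal outlets (empty = control)."""

    occluded_outlets: frozenset[str] = frozenset()

    def __init__(self, occluded_outlets=()) -> None:
        object.__setattr__(self, "occluded_outlets", frozenset(occluded_outlets))

    def validate_against(self, tree: VascularTree) -> None:
        unknown = self.occluded_outlets - set(tree.outlet_order)
        if unknown:
            raise FlowError(f"occluded outlets not in tree: {sorted(unknown)}")

    def __contains__(self, outlet_id: str) -> bool:
        return outlet_id in self.occluded_outlets

    def __len__(self) -> int:
        return len(self.occluded_outlets)


@dataclass(frozen=True)
class FlowSolution:
    """Per-segment flows (and nodal pressures where computed).

    ``node_pressure`` maps the inlet node (``"inlet"``) and each
    segment's distal node (keyed by segment label) to pressure in Pa; it
    is ``None`` in split mode, where no pressure problem is solved.
    ``flow_fraction`` is Q/inlet_flow; in split mode with raw (printed,
    unrenormalized) splits the root fraction equals the sum of the
    splits, which may differ from 1 by rounding of the source table.
    """

    segment_flow: dict[str, float]
    inlet_flow: float
    node_pressure: dict[str, float] | None = None
    reynolds: dict[str, float] = field(default_factory=dict)

    @property
    def flow_fraction(self) -> dict[str, float]:
        return {k: q / self.inlet_flow for k, q in self.segment_flow.items()}

    def outlet_fractions(self, tree: VascularTree) -> dict[str, float]:
        return {
            s.outlet_id: self.segment_flow[s.label] / self.inlet_flow
            for s in tree.terminal_segments
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": k,
                "Q_m3_s": q,
                "fraction": q / self.inlet_flow,
                "reynolds": self.reynolds.get(k, float("nan")),
            }
            for k, q in sorted(self.segment_flow.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SplitTable:
    """Per-outlet flowrates and dimensionless out-splits for one scenario.

    Flowrate magnitudes are treated as relative (the source table's
    declared unit is not physically consistent with the pump setting);
    only the dimensionless out-splits feed the flow model, with the
    absolute inlet flow taken from configuration.
    """

    scenario_name: str
    flowrate: dict[str, float]  # per outlet, table units
    out_split: dict[str, float]  # per outlet, dimensionless
    inlet_flowrate: float

    def __post_init__(self) -> None:
        if set(self.flowrate) != set(self.out_split):
            raise FlowError("flowrate and out_split must cover the same outlets")
        if any(v < 0 for v in self.out_split.values()):
            raise FlowError("out-splits must be non-negative")

    @property
    def outlets(self) -> tuple[str, ...]:
        return tuple(sorted(self.out_split, key=lambda o: int(o.lstrip("O"))))

    def renormalized(self) -> "SplitTable":
        """Copy with out-splits rescaled to sum exactly to 1."""
        total = sum(self.out_split.values())
        if total <= 0:
            raise FlowError("cannot renormalize all-zero splits")
        return SplitTable(
            scenario_name=self.scenario_name,
            flowrate=dict(self.flowrate),
            out_split={k: v / total for k, v in self.out_split.items()},
            inlet_flowrate=self.inlet_flowrate,
        )

    def zero_outlets(self, threshold: float = 0.0) -> frozenset[str]:
        return frozenset(o for o, s in self.out_split.items() if s <= threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario_name,
                "outlet_id": "INLET",
                "flowrate": self.inlet_flowrate,
                "out_split": 1.0,
            }
        ]
        rows += [
            {
                "scenario": self.scenario_name,
                "outlet_id": o,
                "flowrate": self.flowrate[o],
                "out_split": self.out_split[o],
            }
            for o in self.outlets
        ]
        return pd.DataFrame(rows)


def read_split_tables(path: str | Path) -> dict[str, SplitTable]:
    """Read a CSV of scenario/outlet_id/flowrate/out_split rows (one INLET
    row per scenario) into SplitTables keyed by scenario name."""
    df = pd.read_csv(path)
    required = {"scenario", "outlet_id", "flowrate", "out_split"}
    if not required <= set(df.columns):
        raise FlowError(f"split table needs columns {sorted(required)}")
    tables: dict[str, SplitTable] = {}
    for name, grp in df.groupby("scenario", sort=False):
        inlet = grp[grp.outlet_id == "INLET"]
        if len(inlet) != 1:
            raise FlowError(f"scenario {name!r}: need exactly one INLET row")
        outlets = grp[grp.outlet_id != "INLET"]
        tables[name] = SplitTable(
            scenario_name=name,
            flowrate=dict(zip(outlets.outlet_id, outlets.flowrate.astype(float))),
            out_split=dict(zip(outlets.outlet_id, outlets.out_split.astype(float))),
            inlet_flowrate=float(inlet.flowrate.iloc[0]),
        )
    return tables


def write_split_tables(tables: dict[str, SplitTable] | list[SplitTable], path: str | Path) -> None:
    if isinstance(tables, dict):
        tables = list(tables.values())
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)


def segment_resistance(segment: VesselSegment, fluid: FluidProperties) -> float:
    """Hagen-Poiseuille hydraulic resistance 8 mu L / (pi r^4), in Pa s/m^3."""
    if segment.radius <= 0:
        raise FlowError("radius must be positive")
    return 8.0 * fluid.viscosity * segment.length / (math.pi * segment.radius**4)


def reynolds_number(segment: VesselSegment, flow: float, fluid: FluidProperties) -> float:
    """Tube Reynolds number rho V d / mu with V = Q / (pi r^2)."""
    if segment.radius <= 0:
        raise FlowError("radius must be positive")
    velocity = flow / (math.pi * segment.radius**2)
    return fluid.density * velocity * segment.diameter / fluid.viscosity


def _reynolds_map(tree: VascularTree, flows: dict[str, float], fluid: FluidProperties) -> dict[str, float]:
    return {lab: reynolds_number(tree[lab], q, fluid) for lab, q in flows.items()}


def solve_network(
    tree: VascularTree,
    fluid: FluidProperties = WATER,
    bc: FlowBC = FlowBC(),
    occlusion: OcclusionPattern = OcclusionPattern(),
) -> FlowSolution:
    """Solve the Poiseuille resistance network with occlusions.

    Occluded terminals carry exactly zero flow (infinite outlet
    resistance); their dead-end distal nodes take the pressure of their
    parent node. Raises ``FlowError`` if every outlet is blocked.
    """
    occlusion.validate_against(tree)
    open_outlets = [o for o in tree.outlet_order if o not in occlusion]
    if not open_outlets:
        raise FlowError("all outlets occluded: no feasible steady flow")

    inlet_flow = bc.inlet_flow(tree.root)

    # Nodes: "inlet" plus every segment's distal node. Unknown pressures are
    # all nodes except open-outlet distal nodes (Dirichlet reference).
    dirichlet = {tree.segment_for_outlet(o).label for o in open_outlets}
    occluded_terminals = {tree.segment_for_outlet(o).label for o in occlusion.occluded_outlets}
    unknown = ["inlet"] + [
        s.label for s in tree if s.label not in dirichlet and s.label not in occluded_terminals
    ]
    idx = {n: i for i, n in enumerate(unknown)}

    conduct = {
        s.label: 1.0 / segment_resistance(s, fluid)
        for s in tree
        if s.label not in occluded_terminals
    }

    n = len(unknown)
    A = sp.lil_matrix((n, n))
    b = np.zeros(n)
    b[idx["inlet"]] = inlet_flow
    for label, g in conduct.items():
        seg = tree[label]
        up = "inlet" if seg.parent_label is None else seg.parent_label
        down = label
        for a, o in ((up, down), (down, up)):
            if a in idx:
                A[idx[a], idx[a]] += g
                if o in idx:
                    A[idx[a], idx[o]] -= g
                else:
                    b[idx[a]] += g * bc.outlet_pressure

    try:
        p = spsolve(A.tocsr(), b)
    except Exception as exc:  # pragma: no cover - defensive
        raise FlowError(f"singular flow system ({n} unknowns): {exc}") from exc
    if not np.all(np.isfinite(p)):
        raise FlowError("flow system produced non-finite pressures; check the tree")

    pressure = {node: float(p[i]) for node, i in idx.items()}
    for lab in dirichlet:
        pressure[lab] = bc.outlet_pressure

    flows: dict[str, float] = {}
    for s in tree:
        if s.label in occluded_terminals:
            flows[s.label] = 0.0
            parent_node = "inlet" if s.parent_label is None else s.parent_label
            pressure[s.label] = pressure[parent_node]  # static dead end
        else:
            up = "inlet" if s.parent_label is None else s.parent_label
            flows[s.label] = conduct[s.label] * (pressure[up] - pressure[s.label])

    total_out = sum(flows[tree.segment_for_outlet(o).label] for o in open_outlets)
    if abs(total_out - inlet_flow) > 1e-10 * inlet_flow:
        raise FlowError("mass conservation violated in linear solve")

    return FlowSolution(
        segment_flow=flows,
        inlet_flow=inlet_flow,
        node_pressure=pressure,
        reynolds=_reynolds_map(tree, flows, fluid),
    )


def flows_from_splits(
    tree: VascularTree,
    inlet_flow: float,
    splits: SplitTable,
    fluid: FluidProperties = WATER,
) -> FlowSolution:
    """Aggregate measured outlet out-splits up the tree.

    Each segment's flow is ``inlet_flow`` times the sum of the out-splits
    of its downstream outlets, so junction conservation holds exactly by
    construction. No pressure problem is solved in this mode.
    """
    if inlet_flow <= 0:
        raise FlowError("inlet flow must be positive")
    missing = set(tree.outlet_order) - set(splits.out_split)
    if missing:
        raise FlowError(f"split table missing outlets: {sorted(missing)}")
    if sum(splits.out_split.values()) <= 0:
        raise FlowError("all out-splits are zero")

    flows = {
        s.label: inlet_flow
        * sum(splits.out_split[o] for o in downstream_outlets(tree, s.label))
        for s in tree
    }
    return FlowSolution(
        segment_flow=flows,
        inlet_flow=inlet_flow,
        node_pressure=None,
        reynolds=_reynolds_map(tree, flows, fluid),
    )


def mass_balance_residual(splits: SplitTable) -> float:
    """Relative closure error (sum of outlet flowrates - inlet) / inlet."""
    if splits.inlet_flowrate == 0:
        raise FlowError("inlet flowrate is zero")
    return (sum(splits.flowrate.values()) - splits.inlet_flowrate) / splits.inlet_flowrate
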