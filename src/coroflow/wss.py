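"""Per-branch wall shear stress estimation.

Two complementary routes are provided. The Poiseuille closure
``tau = 4 mu Q / (pi r^3)`` gives absolute WSS for fully developed
laminar pipe flow; it understates the area-averaged WSS of a short
entrance-dominated 3D branch (for the inlet channel, ~0.10 Pa vs the
0.36 Pa a full CFD computation reports), so absolute values from it are
reported for transparency rather than validated. The *rescaling* route
exploits the linearity of laminar WSS in flow at fixed geometry: given a
reference scenario's per-branch WSS and branch flow fractions, any other
scenario's WSS follows as ``tau_ref * f_scenario / f_ref``. This is the
route that reproduces the reference CFD tables across occlusion
scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .flow import FluidProperties, FlowError, FlowSolution
from .geometry import VascularTree, VesselSegment, downstream_outlets

__all__ = [
    "WssTable",
    "poiseuille_wss",
    "wss_from_solution",
    "branch_fractions",
    "rescale_wss",
    "wss_summary",
]


class WssError(ValueError):
    """Invalid WSS table or rescaling inputs."""


@dataclass(frozen=True)
class WssTable:
    """Area-averaged WSS per branch for one scenario.

    ``provenance`` records how values were obtained: ``"model"``
    (Poiseuille closure), ``"reference"`` (external CFD/measured table),
    or ``"rescaled"`` (flow-fraction rescaling of a reference).
    """

    scenario_name: str
    wss: dict[str, float]  # Pa, keyed by branch label
    provenance: str = "model"

    def __post_init__(self) -> None:
        if self.provenance not in ("model", "reference", "rescaled"):
            raise WssError(f"unknown provenance {self.provenance!r}")
        if any(v < 0 for v in self.wss.values()):
            raise WssError("WSS values must be non-negative")
        if not self.wss:
            raise WssError("empty WSS table")

    def __getitem__(self, branch: str) -> float:
        try:
            return self.wss[branch]
        except KeyError:
            raise WssError(f"branch {branch!r} not in table") from None

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Half-away-from-zero rounding, matching printed-table formatting."""
        factor = 10.0**decimals
        return {b: math.floor(v * factor + 0.5) / factor for b, v in self.wss.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "branch": b,
                    "scenario": self.scenario_name,
                    "wss_pa": v,
                    "provenance": self.provenance,
                }
                for b, v in sorted(self.wss.items())
            ]
        )


def read_wss_tables(path) -> dict[str, WssTable]:
    """Read branch/scenario/wss_pa/provenance CSV into tables by scenario."""
    df = pd.read_csv(path)
    required = {"branch", "scenario", "wss_pa"}
    if not required <= set(df.columns):
        raise WssError(f"WSS table needs columns {sorted(required)}")
    tables: dict[str, WssTable] = {}
    for name, grp in df.groupby("scenario", sort=False):
        prov = grp["provenance"].iloc[0] if "provenance" in grp else "reference"
        tables[name] = WssTable(
            scenario_name=name,
            wss=dict(zip(grp.branch, grp.wss_pa.astype(float))),
            provenance=prov,
        )
    return tables


def poiseuille_wss(segment: VesselSegment, flow: float, fluid: FluidProperties) -> float:
    """Fully developed laminar wall shear stress 4 mu Q / (pi r^3), in Pa."""
    if segment.radius <= 0:
        raise WssError("radius must be positive")
    if flow < 0:
        raise WssError("flow must be non-negative")
    return 4.0 * fluid.viscosity * flow / (math.pi * segment.radius**3)


def wss_from_solution(
    tree: VascularTree,
    solution: FlowSolution,
    fluid: FluidProperties,
    scenario_name: str = "model",
) -> WssTable:
    """Poiseuille WSS for every segment of a flow solution."""
    return WssTable(
        scenario_name=scenario_name,
        wss={
            s.label: poiseuille_wss(s, solution.segment_flow[s.label], fluid) for s in tree
        },
        provenance="model",
    )


def branch_fractions(tree: VascularTree, out_splits: Mapping[str, float]) -> dict[str, float]:
    """Per-branch flow fraction: the sum of outlet out-splits downstream of
    each segment (the root collects them all)."""
    missing = set(tree.outlet_order) - set(out_splits)
    if missing:
        raise FlowError(f"out-splits missing outlets: {sorted(missing)}")
    return {
        s.label: sum(out_splits[o] for o in downstream_outlets(tree, s.label)) for s in tree
    }


def rescale_wss(
    reference: WssTable,
    reference_fractions: Mapping[str, float],
    scenario_fractions: Mapping[str, float],
    scenario_name: str | None = None,
) -> WssTable:
    """Rescale a reference WSS table to another scenario's flow fractions.

    ``tau_scenario(b) = tau_ref(b) * f_scenario(b) / f_ref(b)``; branches
    with zero scenario fraction get exactly zero. Every branch of the
    reference table must appear in both fraction maps, and branches with
    nonzero reference WSS need a positive reference fraction.
    """
    out: dict[str, float] = {}
    for branch, tau in reference.wss.items():
        if branch not in reference_fractions or branch not in scenario_fractions:
            raise WssError(f"branch {branch!r} missing from fraction maps")
        f_s = scenario_fractions[branch]
        if f_s == 0.0:
            out[branch] = 0.0
            continue
        f_r = reference_fractions[branch]
        if f_r <= 0.0 and tau > 0.0:
            raise WssError(f"branch {branch!r}: nonzero reference WSS with zero reference flow")
        out[branch] = tau * f_s / f_r if f_r > 0 else 0.0
    return WssTable(
        scenario_name=scenario_name or reference.scenario_name,
        wss=out,
        provenance="rescaled",
    )


def wss_summary(table: WssTable, zero_threshold: float = 0.05) -> dict:
    """Max/min branches, zero-branch count and mean over nonzero branches.

    ``zero_threshold`` (Pa) separates genuinely perfused branches from
    the near-zero values that numerical residue leaves in occluded ones.
    """
    if not table.wss:
        raise WssError("empty WSS table")
    items = sorted(table.wss.items())
    max_branch, max_wss = max(items, key=lambda kv: kv[1])
    min_branch, min_wss = min(items, key=lambda kv: kv[1])
    nonzero = [v for _, v in items if v > zero_threshold]
    return {
        "scenario": table.scenario_name,
        "max_branch": max_branch,
        "max_wss_pa": max_wss,
        "min_branch": min_branch,
        "min_wss_pa": min_wss,
        "n_zero_branches": sum(1 for _, v in items if v <= zero_threshold),
        "mean_nonzero_wss_pa": sum(nonzero) / len(nonzero) if nonzero else 0.0,
    }
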