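"""Perfusion-impairment scenarios and the end-to-end pipeline.

The built-in study mirrors the four measured perfusion states of the
microfluidic experiment: a homogeneous control and three asymmetric
occlusion patterns blocking one, three and five of the eight outlets
(``case_1/8``, ``case_3/8``, ``case_5/8``). Occlusion sets are
reconstructed from the zero rows of the measured out-split table; the
reconstruction is cross-checked against the zero-WSS entries of the
reference table in the test suite.

:func:`run_pipeline` builds the tree once, computes per-scenario flows
(either from measured splits or from the resistance model), derives WSS
both ways (Poiseuille absolute and rescaled against the control
reference), and assembles ratios and zero-flow counts for comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .flow import (
    FlowBC,
    FlowSolution,
    FluidProperties,
    OcclusionPattern,
    SplitTable,
    flows_from_splits,
    read_split_tables,
    solve_network,
)
from .geometry import GeometryConfig, build_tree
from .wss import WssTable, branch_fractions, read_wss_tables, rescale_wss, wss_from_solution

__all__ = [
    "PerfusionScenario",
    "ScenarioComparison",
    "builtin_scenarios",
    "builtin_split_tables",
    "reference_wss_tables",
    "run_pipeline",
    "compensation_index",
    "write_reports",
    "run_study",
]

SCENARIO_NAMES = ("control", "case_1/8", "case_3/8", "case_5/8")

#: Occlusion sets of the built-in scenarios, as reconstructed from the
#: zero rows of the measured out-split table.
BUILTIN_OCCLUSIONS: dict[str, frozenset[str]] = {
    "control": frozenset(),
    "case_1/8": frozenset({"O3"}),
    "case_3/8": frozenset({"O1", "O2", "O3"}),
    "case_5/8": frozenset({"O1", "O2", "O3", "O5", "O8"}),
}


class ScenarioError(ValueError):
    """Invalid scenario or pipeline configuration."""


@dataclass(frozen=True)
class PerfusionScenario:
    """A named occlusion pattern with optional measured out-splits."""

    name: str
    occlusion: OcclusionPattern = OcclusionPattern()
    measured_splits: SplitTable | None = None

    def __post_init__(self) -> None:
        if self.measured_splits is not None:
            bad = [
                o
                for o in self.occlusion.occluded_outlets
                if self.measured_splits.out_split.get(o, 0.0) != 0.0
            ]
            if bad:
                raise ScenarioError(
                    f"scenario {self.name!r}: occluded outlets with nonzero splits: {sorted(bad)}"
                )


def _data_path(name: str):
    return resources.files("coroflow.data").joinpath(name)


def builtin_split_tables() -> dict[str, SplitTable]:
    """The packaged measured out-split tables, one per scenario."""
    with resources.as_file(_data_path("outlet_splits.csv")) as p:
        return read_split_tables(p)


def reference_wss_tables() -> dict[str, WssTable]:
    """The packaged reference (CFD-derived) per-branch WSS tables."""
    with resources.as_file(_data_path("reference_wss.csv")) as p:
        return read_wss_tables(p)


def builtin_scenarios() -> list[PerfusionScenario]:
    """The four built-in perfusion states with measured splits attached."""
    splits = builtin_split_tables()
    return [
        PerfusionScenario(
            name=name,
            occlusion=OcclusionPattern(BUILTIN_OCCLUSIONS[name]),
            measured_splits=splits[name],
        )
        for name in SCENARIO_NAMES
    ]


@dataclass(frozen=True)
class ScenarioComparison:
    """Cross-scenario results of one pipeline run."""

    scenario_names: tuple[str, ...]
    reference_name: str
    rescaled_wss: dict[str, WssTable]
    poiseuille_wss: dict[str, WssTable]
    wss_ratio: dict[str, dict[str, float]]  # vs reference, per branch
    split_ratio: dict[str, dict[str, float]]  # vs reference, per outlet
    outlet_fractions: dict[str, dict[str, float]]
    zero_flow_counts: dict[str, int]
    solutions: dict[str, FlowSolution] = field(compare=False, default_factory=dict)


def _zero_flow_count(fractions: dict[str, float], tol: float = 0.0) -> int:
    return sum(1 for v in fractions.values() if v <= tol)


def run_pipeline(
    scenarios: list[PerfusionScenario] | None = None,
    config: GeometryConfig = GeometryConfig(),
    fluid: FluidProperties = FluidProperties(),
    bc: FlowBC = FlowBC(),
    mode: str = "splits",
    reference_wss: WssTable | None = None,
    reference_name: str = "control",
) -> ScenarioComparison:
    """Run tree -> flows -> WSS -> comparison for a list of scenarios.

    ``mode="splits"`` drives each scenario with its measured out-splits
    (every scenario must then carry a split table); ``mode="resistance"``
    predicts flows from the occlusion pattern alone. WSS is rescaled from
    ``reference_wss`` (default: the packaged control reference table)
    using the reference scenario's branch fractions, with Poiseuille
    absolute values computed alongside. Deterministic given its inputs.
    """
    if scenarios is None:
        scenarios = builtin_scenarios()
    if not scenarios:
        raise ScenarioError("no scenarios given")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ScenarioError("scenario names must be unique")
    if reference_name not in names:
        raise ScenarioError(f"reference scenario {reference_name!r} not among {names}")
    if mode not in ("splits", "resistance"):
        raise ScenarioError(f"unknown mode {mode!r}")
    if mode == "splits":
        missing = [s.name for s in scenarios if s.measured_splits is None]
        if missing:
            raise ScenarioError(f"splits mode needs measured splits for: {missing}")
    if reference_wss is None:
        reference_wss = reference_wss_tables()[reference_name]

    tree = build_tree(config)
    inlet_flow = bc.inlet_flow(tree.root)

    solutions: dict[str, FlowSolution] = {}
    fractions: dict[str, dict[str, float]] = {}
    for sc in scenarios:
        if mode == "splits":
            sol = flows_from_splits(tree, inlet_flow, sc.measured_splits, fluid)
            fractions[sc.name] = branch_fractions(tree, sc.measured_splits.out_split)
        else:
            sol = solve_network(tree, fluid, bc, sc.occlusion)
            fractions[sc.name] = sol.flow_fraction
        solutions[sc.name] = sol

    ref_fr = fractions[reference_name]
    rescaled = {
        sc.name: rescale_wss(reference_wss, ref_fr, fractions[sc.name], sc.name)
        for sc in scenarios
    }
    poiseuille = {
        sc.name: wss_from_solution(tree, solutions[sc.name], fluid, sc.name)
        for sc in scenarios
    }

    wss_ratio = {
        name: {
            b: (rescaled[name][b] / reference_wss[b] if reference_wss[b] > 0 else 0.0)
            for b in reference_wss.wss
        }
        for name in names
    }
    outlet_fr = {name: solutions[name].outlet_fractions(tree) for name in names}
    ref_out = outlet_fr[reference_name]
    split_ratio = {
        name: {
            o: (outlet_fr[name][o] / ref_out[o] if ref_out[o] > 0 else 0.0)
            for o in tree.outlet_order
        }
        for name in names
    }
    zero_counts = {name: _zero_flow_count(fractions[name]) for name in names}

    return ScenarioComparison(
        scenario_names=tuple(names),
        reference_name=reference_name,
        rescaled_wss=rescaled,
        poiseuille_wss=poiseuille,
        wss_ratio=wss_ratio,
        split_ratio=split_ratio,
        outlet_fractions=outlet_fr,
        zero_flow_counts=zero_counts,
        solutions=solutions,
    )


def compensation_index(comparison: ScenarioComparison, scenario: str) -> float:
    """Largest per-outlet split ratio of a scenario versus the reference.

    Open outlets in an occluded scenario take over the flow the blocked
    ones lose; the maximum ratio of scenario to reference out-split over
    the still-open outlets quantifies that redistribution (1.0 means no
    compensation).
    """
    if scenario not in comparison.split_ratio:
        raise ScenarioError(f"unknown scenario {scenario!r}")
    open_ratios = [
        r
        for o, r in comparison.split_ratio[scenario].items()
        if comparison.outlet_fractions[scenario][o] > 0
    ]
    if not open_ratios:
        raise ScenarioError(f"scenario {scenario!r} has no open outlets")
    return max(open_ratios)


def _comparison_frames(comparison: ScenarioComparison) -> tuple[pd.DataFrame, pd.DataFrame]:
    branches = sorted(next(iter(comparison.rescaled_wss.values())).wss)
    wss = pd.DataFrame(
        {
            name: [comparison.rescaled_wss[name][b] for b in branches]
            for name in comparison.scenario_names
        },
        index=pd.Index(branches, name="branch"),
    )
    ratios = pd.DataFrame(
        {
            name: [comparison.wss_ratio[name][b] for b in branches]
            for name in comparison.scenario_names
        },
        index=pd.Index(branches, name="branch"),
    )
    return wss, ratios


def write_reports(comparison: ScenarioComparison, outdir: str | Path) -> dict[str, Path]:
    """Write comparison.csv (branch x scenario rescaled WSS), ratios.csv and
    summary.json; output is byte-stable for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wss, ratios = _comparison_frames(comparison)
    paths = {
        "comparison": outdir / "comparison.csv",
        "ratios": outdir / "ratios.csv",
        "summary": outdir / "summary.json",
    }
    wss.round(6).to_csv(paths["comparison"], float_format="%.6f")
    ratios.round(6).to_csv(paths["ratios"], float_format="%.6f")
    summary = {
        "reference": comparison.reference_name,
        "zero_flow_counts": dict(sorted(comparison.zero_flow_counts.items())),
        "compensation_index": {
            name: round(compensation_index(comparison, name), 6)
            for name in comparison.scenario_names
        },
        "outlet_fractions": {
            name: {o: round(v, 6) for o, v in sorted(fr.items())}
            for name, fr in sorted(comparison.outlet_fractions.items())
        },
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def run_study(config_path: str | Path) -> ScenarioComparison:
    """Run a study described by a YAML file.

    Recognized keys (all optional, with built-in defaults): ``geometry``
    (GeometryConfig fields), ``fluid`` (density, viscosity), ``bc``
    (FlowBC fields), ``mode``, ``scenarios`` (list of {name, occlude,
    splits_file} — omit for the built-in four), ``output_dir``.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    geometry = GeometryConfig(**{
        k: (tuple(v) if k == "length_fractions" and v is not None else v)
        for k, v in (cfg.get("geometry") or {}).items()
    })
    fluid = FluidProperties(**(cfg.get("fluid") or {}))
    bc = FlowBC(**(cfg.get("bc") or {}))
    mode = cfg.get("mode", "splits")

    if "scenarios" in cfg:
        scenario_list = []
        for item in cfg["scenarios"]:
            splits = None
            if item.get("splits_file"):
                tables = read_split_tables(item["splits_file"])
                splits = tables.get(item["name"]) or next(iter(tables.values()))
            scenario_list.append(
                PerfusionScenario(
                    name=item["name"],
                    occlusion=OcclusionPattern(item.get("occlude", ())),
                    measured_splits=splits,
                )
            )
    else:
        scenario_list = builtin_scenarios()

    comparison = run_pipeline(scenario_list, geometry, fluid, bc, mode=mode)
    if cfg.get("output_dir"):
        write_reports(comparison, cfg["output_dir"])
    return comparison
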