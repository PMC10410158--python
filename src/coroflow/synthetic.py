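"""Synthetic outlet volume-collection measurements.

Emulates the experiment that produced the measured out-split tables: the
pump drives a known flowrate through the tree for a fixed collection
time, the volume at each open outlet is measured, and out-splits are the
volumes normalized by the measured total. Two noise sources are modeled:

* measurement noise, multiplicative on collected volume (pipetting and
  meniscus-reading errors scale with volume), default relative sd 0.03 —
  calibrated to the spread of the measured control out-splits
  (0.121–0.129 around the ideal 0.125);
* fabrication jitter on channel widths, Gaussian with a default sd such
  that 20 µm is the ~99th-percentile absolute width deviation, matching
  the reported maximum channel-width variability of the printed devices.

Occluded outlets collect exactly zero volume (the blocking syringes
admit no flow). All randomness flows from a single seed through
per-outlet (or per-segment) substreams derived by counter, so adding
outlets never reshuffles existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .flow import FlowBC, FlowError, FluidProperties, OcclusionPattern, SplitTable, solve_network
from .geometry import VascularTree, VesselSegment

__all__ = [
    "NoiseModel",
    "FabricationJitter",
    "perturb_geometry",
    "simulate_measurements",
    "detect_occlusions",
]

#: Width sd (m) placing the reported 20 µm maximum at the 99th percentile
#: of |width deviation| (20e-6 / Phi^-1(0.995)).
DEFAULT_WIDTH_SD = 20e-6 / 2.5758293035489004


class SyntheticError(ValueError):
    """Invalid noise configuration or infeasible simulation."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise on collected volumes."""

    relative_sd: float = 0.03
    distribution: str = "gaussian-truncated-at-zero"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise SyntheticError("relative sd must be non-negative")
        if self.distribution not in ("gaussian-truncated-at-zero", "lognormal"):
            raise SyntheticError(f"unknown distribution {self.distribution!r}")

    def factors(self, n: int) -> np.ndarray:
        """One multiplicative factor per outlet, via per-outlet substreams."""
        out = np.empty(n)
        for i in range(n):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(i,)))
            if self.distribution == "lognormal":
                # mean-one lognormal with relative sd ~ relative_sd
                sigma = np.sqrt(np.log1p(self.relative_sd**2))
                out[i] = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
            else:
                out[i] = max(0.0, 1.0 + rng.normal(0.0, self.relative_sd))
        return out


@dataclass(frozen=True)
class FabricationJitter:
    """Gaussian channel-width variability of the fabricated device."""

    width_sd: float = DEFAULT_WIDTH_SD  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_sd < 0:
            raise SyntheticError("width sd must be non-negative")


def perturb_geometry(tree: VascularTree, jitter: FabricationJitter) -> VascularTree:
    """Copy of ``tree`` with each segment radius independently jittered.

    Width deviations are drawn per segment (substream by segment index in
    label-sorted order); the radius shift is half the width shift. Draws
    that would make a radius non-positive are rejected with an error —
    they indicate a jitter scale incompatible with the geometry.
    """
    if jitter.width_sd == 0.0:
        return tree
    labels = sorted(tree.segments)
    segments: dict[str, VesselSegment] = {}
    for i, label in enumerate(labels):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=jitter.seed, spawn_key=(i,))
        )
        seg = tree.segments[label]
        delta_radius = 0.5 * rng.normal(0.0, jitter.width_sd)
        new_radius = seg.radius + delta_radius
        if new_radius <= 0:
            raise SyntheticError(
                f"jitter draw drives segment {label} radius non-positive "
                f"({new_radius:.3e} m); reduce width_sd"
            )
        segments[label] = replace(seg, radius=new_radius)
    return VascularTree(
        segments=segments,
        root_label=tree.root_label,
        outlet_order=tree.outlet_order,
        config=tree.config,
    )


def simulate_measurements(
    tree: VascularTree,
    fluid: FluidProperties = FluidProperties(),
    pump_rate: float = 195e-9 / 60.0,
    occlusion: OcclusionPattern = OcclusionPattern(),
    noise: NoiseModel = NoiseModel(),
    duration: float = 60.0,
    scenario_name: str = "simulated",
) -> SplitTable:
    """One synthetic volume-collection run.

    Solves the resistance network at ``pump_rate`` with the given
    occlusions, collects outlet volumes over ``duration`` seconds,
    applies multiplicative measurement noise per outlet, zeroes the
    occluded outlets exactly, and normalizes by the measured total.
    Deterministic given the noise seed.
    """
    if pump_rate <= 0:
        raise SyntheticError("pump rate must be positive")
    if duration <= 0:
        raise SyntheticError("duration must be positive")
    bc = FlowBC(inlet_mode="flowrate", inlet_flowrate=pump_rate)
    try:
        solution = solve_network(tree, fluid, bc, occlusion)
    except FlowError as exc:
        raise SyntheticError(str(exc)) from exc

    outlets = list(tree.outlet_order)
    true_flows = np.array(
        [solution.segment_flow[tree.segment_for_outlet(o).label] for o in outlets]
    )
    volumes = true_flows * duration * noise.factors(len(outlets))
    occluded = np.array([o in occlusion for o in outlets])
    volumes[occluded] = 0.0
    total = volumes.sum()
    if total <= 0:
        raise SyntheticError("no volume collected at any outlet")
    splits = volumes / total
    return SplitTable(
        scenario_name=scenario_name,
        flowrate=dict(zip(outlets, (volumes / duration).tolist())),
        out_split=dict(zip(outlets, splits.tolist())),
        inlet_flowrate=float(volumes.sum() / duration),
    )


def detect_occlusions(splits: SplitTable, threshold: float = 0.01) -> OcclusionPattern:
    """Outlets whose out-split does not exceed ``threshold`` (default 0.01)."""
    if not 0 <= threshold < 1:
        raise SyntheticError("threshold must lie in [0, 1)")
    return OcclusionPattern(
        o for o, s in splits.out_split.items() if s <= threshold
    )
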