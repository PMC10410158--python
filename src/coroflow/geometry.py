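"""Idealized coronary microvascular tree geometry.

The network is a rooted symmetric binary tree of straight cylindrical
segments: an inlet channel ``C1`` followed by ``n_generations`` of
bifurcations. Radii taper by a generalized Murray rule
``r_parent^m = sum(r_child^m)`` with equal children, so each generation
shrinks radii by the factor ``2**(-1/m)``. With the classical exponent
``m = 3`` this is Murray's law proper, which implies equal wall shear
stress in every segment under equal flow splits.

Branch labels follow the channel/bifurcated-vessel convention: the inlet
channel is ``C1``; generation ``g >= 2`` holds ``2**(g-1)`` segments
labeled ``Cg-Bk`` left-to-right; the terminal segment ``Bk`` drains
outlet ``Ok``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "GeometryConfig",
    "VesselSegment",
    "VascularTree",
    "murray_child_radius",
    "infer_murray_exponent",
    "build_tree",
    "downstream_outlets",
    "planar_layout",
    "export_tree",
    "load_tree",
]


class GeometryError(ValueError):
    """Invalid geometric configuration or tree query."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the idealized tree.

    ``murray_exponent=None`` (the default) infers the taper exponent from
    the endpoint diameters so that both the inlet and outlet diameters are
    honored exactly; for the default 1 mm -> 0.4 mm over 3 generations this
    gives m ~ 2.2694. Pass ``murray_exponent=3.0`` for the strict Murray
    taper (which makes the printed outlet diameter nominal: 3 generations
    from 1 mm then end at 0.5 mm).

    ``length_fractions`` distributes ``total_path_length`` over the
    ``n_generations + 1`` segment levels along any root-to-outlet path;
    the default is equal fractions.
    """

    inlet_diameter: float = 1.0e-3
    outlet_diameter: float = 0.4e-3
    n_generations: int = 3
    total_path_length: float = 1.0e-2
    murray_exponent: float | None = None
    bifurcation_half_angle: float = 30.0
    length_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.inlet_diameter <= 0 or self.outlet_diameter <= 0:
            raise GeometryError("diameters must be positive")
        if self.outlet_diameter >= self.inlet_diameter:
            raise GeometryError("outlet diameter must be smaller than inlet diameter")
        if self.n_generations < 1:
            raise GeometryError("need at least one bifurcation generation")
        if self.total_path_length <= 0:
            raise GeometryError("total path length must be positive")
        if self.murray_exponent is not None and self.murray_exponent <= 0:
            raise GeometryError("Murray exponent must be positive")
        if self.length_fractions is not None:
            fr = tuple(self.length_fractions)
            if len(fr) != self.n_levels:
                raise GeometryError(
                    f"length_fractions needs {self.n_levels} entries, got {len(fr)}"
                )
            if any(f <= 0 for f in fr):
                raise GeometryError("length fractions must be positive")
            if abs(sum(fr) - 1.0) > 1e-12:
                raise GeometryError("length fractions must sum to 1")
            object.__setattr__(self, "length_fractions", fr)

    @property
    def n_levels(self) -> int:
        """Number of segment levels along a root-to-outlet path."""
        return self.n_generations + 1

    @property
    def n_outlets(self) -> int:
        return 2**self.n_generations

    def effective_exponent(self) -> float:
        """The taper exponent actually used when building the tree."""
        if self.murray_exponent is not None:
            return self.murray_exponent
        return infer_murray_exponent(
            self.inlet_diameter, self.outlet_diameter, self.n_generations
        )

    def level_lengths(self) -> tuple[float, ...]:
        fr = self.length_fractions or tuple([1.0 / self.n_levels] * self.n_levels)
        return tuple(f * self.total_path_length for f in fr)


@dataclass(frozen=True)
class VesselSegment:
    """One cylindrical vessel segment of the tree."""

    label: str
    generation: int  # 1 = inlet channel
    radius: float  # m
    length: float  # m
    parent_label: str | None = None
    child_labels: tuple[str, ...] = ()
    outlet_id: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise GeometryError(f"segment {self.label}: radius and length must be positive")
        if self.outlet_id is not None and self.child_labels:
            raise GeometryError(f"segment {self.label}: terminal segments have no children")

    @property
    def is_terminal(self) -> bool:
        return self.outlet_id is not None

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class VascularTree:
    """Labeled bifurcating tree of vessel segments."""

    segments: dict[str, VesselSegment]
    root_label: str
    outlet_order: tuple[str, ...]
    config: GeometryConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.root_label not in self.segments:
            raise GeometryError("root label missing from segments")
        for seg in self.segments.values():
            if seg.parent_label is None and seg.label != self.root_label:
                raise GeometryError(f"segment {seg.label} has no parent but is not the root")
            if seg.parent_label is not None and seg.parent_label not in self.segments:
                raise GeometryError(f"segment {seg.label}: unknown parent {seg.parent_label}")
            for c in seg.child_labels:
                if c not in self.segments:
                    raise GeometryError(f"segment {seg.label}: unknown child {c}")

    def __getitem__(self, label: str) -> VesselSegment:
        try:
            return self.segments[label]
        except KeyError:
            raise GeometryError(f"unknown segment label {label!r}") from None

    def __iter__(self):
        return iter(self.segments.values())

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def root(self) -> VesselSegment:
        return self.segments[self.root_label]

    @property
    def terminal_segments(self) -> tuple[VesselSegment, ...]:
        by_outlet = {s.outlet_id: s for s in self.segments.values() if s.is_terminal}
        return tuple(by_outlet[o] for o in self.outlet_order)

    def segment_for_outlet(self, outlet_id: str) -> VesselSegment:
        for seg in self.terminal_segments:
            if seg.outlet_id == outlet_id:
                return seg
        raise GeometryError(f"unknown outlet id {outlet_id!r}")

    def path_to_outlet(self, outlet_id: str) -> tuple[VesselSegment, ...]:
        """Segments from the root down to (and including) the outlet's terminal."""
        seg = self.segment_for_outlet(outlet_id)
        path = [seg]
        while seg.parent_label is not None:
            seg = self.segments[seg.parent_label]
            path.append(seg)
        return tuple(reversed(path))


def murray_child_radius(parent_radius: float, n_children: int, exponent: float) -> float:
    """Radius of each of ``n_children`` equal daughters under the generalized
    Murray rule ``n * r_c**m = r_p**m``."""
    if parent_radius <= 0:
        raise GeometryError("parent radius must be positive")
    if n_children < 1:
        raise GeometryError("need at least one child")
    if exponent <= 0:
        raise GeometryError("exponent must be positive")
    return parent_radius * n_children ** (-1.0 / exponent)


def infer_murray_exponent(
    inlet_diameter: float, outlet_diameter: float, n_generations: int
) -> float:
    """Taper exponent m under which ``n_generations`` equal-split bifurcations
    map the inlet diameter onto the outlet diameter.

    Solves ``(d_in/d_out)**(m/n) = 2``, i.e. ``m = n ln 2 / ln(d_in/d_out)``.
    """
    if not 0 < outlet_diameter < inlet_diameter:
        raise GeometryError("require 0 < outlet diameter < inlet diameter")
    if n_generations < 1:
        raise GeometryError("need at least one generation")
    return n_generations * math.log(2.0) / math.log(inlet_diameter / outlet_diameter)


def build_tree(config: GeometryConfig) -> VascularTree:
    """Construct the symmetric bifurcating tree for ``config``.

    Returns a tree with ``2**n_generations`` outlets; radii follow repeated
    :func:`murray_child_radius` with the effective exponent, and segment
    lengths along every root-to-outlet path sum to ``total_path_length``.
    """
    m = config.effective_exponent()
    lengths = config.level_lengths()
    shrink = 2.0 ** (-1.0 / m)
    n_levels = config.n_levels

    segments: dict[str, VesselSegment] = {}
    root_radius = config.inlet_diameter / 2.0

    def label_for(level: int, k: int) -> str:
        return "C1" if level == 1 else f"C{level}-B{k}"

    for level in range(1, n_levels + 1):
        radius = root_radius * shrink ** (level - 1)
        n_branches = 2 ** (level - 1)
        for k in range(1, n_branches + 1):
            label = label_for(level, k)
            parent = None if level == 1 else label_for(level - 1, (k + 1) // 2)
            if level < n_levels:
                children = (label_for(level + 1, 2 * k - 1), label_for(level + 1, 2 * k))
                outlet = None
            else:
                children = ()
                outlet = f"O{k}"
            segments[label] = VesselSegment(
                label=label,
                generation=level,
                radius=radius,
                length=lengths[level - 1],
                parent_label=parent,
                child_labels=children,
                outlet_id=outlet,
            )

    outlet_order = tuple(f"O{k}" for k in range(1, config.n_outlets + 1))
    return VascularTree(
        segments=segments, root_label="C1", outlet_order=outlet_order, config=config
    )


def downstream_outlets(tree: VascularTree, label: str) -> frozenset[str]:
    """Outlet ids reachable from ``label`` (the root reaches all outlets)."""
    seg = tree[label]
    if seg.is_terminal:
        return frozenset({seg.outlet_id})
    out: set[str] = set()
    for c in seg.child_labels:
        out |= downstream_outlets(tree, c)
    return frozenset(out)


def planar_layout(tree: VascularTree) -> dict[str, tuple[float, float]]:
    """Planar node coordinates for export/plotting only.

    Nodes are the inlet point (``"inlet"``) plus each segment's distal
    point (keyed by segment label). The root points in -y; at each
    bifurcation the children deviate by +/- the configured half-angle,
    halved per generation so outlets fan out left-to-right without
    crossing. The layout has no effect on the flow model.
    """
    half = (tree.config.bifurcation_half_angle if tree.config else 30.0) * math.pi / 180.0
    coords: dict[str, tuple[float, float]] = {"inlet": (0.0, 0.0)}

    def place(label: str, origin: tuple[float, float], angle: float, depth: int) -> None:
        seg = tree[label]
        end = (
            origin[0] + seg.length * math.sin(angle),
            origin[1] - seg.length * math.cos(angle),
        )
        coords[label] = end
        spread = half / 2**depth
        for c, sign in zip(seg.child_labels, (-1.0, 1.0)):
            place(c, end, angle + sign * spread, depth + 1)

    place(tree.root_label, coords["inlet"], 0.0, 0)
    return coords


def _tree_to_dict(tree: VascularTree) -> dict:
    return {
        "segments": [
            {
                "label": s.label,
                "generation": s.generation,
                "radius_m": s.radius,
                "length_m": s.length,
                "parent": s.parent_label,
                "children": list(s.child_labels),
                "outlet": s.outlet_id,
            }
            for s in sorted(tree.segments.values(), key=lambda s: (s.generation, s.label))
        ],
        "root": tree.root_label,
        "outlet_order": list(tree.outlet_order),
    }


def _tree_from_dict(data: dict) -> VascularTree:
    segments = {
        rec["label"]: VesselSegment(
            label=rec["label"],
            generation=rec["generation"],
            radius=rec["radius_m"],
            length=rec["length_m"],
            parent_label=rec["parent"],
            child_labels=tuple(rec["children"]),
            outlet_id=rec["outlet"],
        )
        for rec in data["segments"]
    }
    return VascularTree(
        segments=segments,
        root_label=data["root"],
        outlet_order=tuple(data["outlet_order"]),
    )


def export_tree(tree: VascularTree, path, format: str = "json") -> None:
    """Write the centerline tree to ``path`` as ``json`` (lossless round-trip)
    or ``vtk-polyline`` (legacy ASCII VTK with a ``radius_m`` point array)."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_tree_to_dict(tree), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "vtk-polyline":
        coords = planar_layout(tree)
        node_ids = ["inlet"] + [
            s.label for s in sorted(tree.segments.values(), key=lambda s: (s.generation, s.label))
        ]
        index = {n: i for i, n in enumerate(node_ids)}
        # radius at the inlet point is the root radius; elsewhere the segment's
        radii = {"inlet": tree.root.radius}
        radii.update({s.label: s.radius for s in tree})
        lines = [
            "# vtk DataFile Version 3.0",
            "vascular tree centerline",
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {len(node_ids)} double",
        ]
        for n in node_ids:
            x, y = coords[n]
            lines.append(f"{x:.9e} {y:.9e} 0.0")
        lines.append(f"LINES {len(tree)} {3 * len(tree)}")
        for s in sorted(tree.segments.values(), key=lambda s: (s.generation, s.label)):
            start = "inlet" if s.parent_label is None else s.parent_label
            lines.append(f"2 {index[start]} {index[s.label]}")
        lines += [
            f"POINT_DATA {len(node_ids)}",
            "SCALARS radius_m double 1",
            "LOOKUP_TABLE default",
        ]
        lines += [f"{radii[n]:.9e}" for n in node_ids]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise GeometryError(f"unsupported export format {format!r}")


def load_tree(path) -> VascularTree:
    """Read a tree previously written by :func:`export_tree` (JSON format)."""
    with open(path) as fh:
        return _tree_from_dict(json.load(fh))
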