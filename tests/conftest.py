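import math

import pytest

from coroflow import (
    FluidProperties,
    GeometryConfig,
    build_tree,
    builtin_split_tables,
    reference_wss_tables,
    segment_resistance,
)


@pytest.fixture(scope="session")
def water():
    return FluidProperties()


@pytest.fixture(scope="session")
def default_tree():
    """Default 3-generation tree: 1 mm inlet, 0.4 mm outlets, 1 cm paths."""
    return build_tree(GeometryConfig())


@pytest.fixture(scope="session")
def murray3_tree():
    """Strict exponent-3 Murray taper (terminal diameter 0.5 mm nominal)."""
    return build_tree(GeometryConfig(murray_exponent=3.0))


@pytest.fixture(scope="session")
def split_tables():
    return builtin_split_tables()


@pytest.fixture(scope="session")
def wss_reference():
    return reference_wss_tables()


def series_parallel_flows(tree, fluid, inlet_flow, occluded):
    """Independent oracle: recursive series-parallel resistance reduction.

    Terminal segments are their own Poiseuille resistance (infinite when
    occluded); an interior segment is its resistance in series with the
    parallel combination of its children's effective resistances. Flow is
    distributed down the tree proportionally to child conductances.
    """
    occluded = set(occluded)

    def effective(label):
        seg = tree[label]
        own = segment_resistance(seg, fluid)
        if seg.is_terminal:
            return math.inf if seg.outlet_id in occluded else own
        g = sum(
            0.0 if math.isinf(r) else 1.0 / r
            for r in (effective(c) for c in seg.child_labels)
        )
        return math.inf if g == 0.0 else own + 1.0 / g

    flows = {}

    def distribute(label, flow):
        flows[label] = flow
        seg = tree[label]
        if seg.is_terminal:
            return
        conduct = {
            c: (0.0 if math.isinf(r) else 1.0 / r)
            for c, r in ((c, effective(c)) for c in seg.child_labels)
        }
        total = sum(conduct.values())
        for c in seg.child_labels:
            distribute(c, flow * conduct[c] / total if total > 0 else 0.0)

    if math.isinf(effective(tree.root_label)):
        raise ValueError("all outlets occluded")
    distribute(tree.root_label, inlet_flow)
    return flows
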