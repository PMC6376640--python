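from collections import OrderedDict

import networkx as nx
import pytest

from enrichgrid import (
    AnnotationGraph,
    Condition,
    FixtureSpec,
    GeneAnnotation,
    ThreeLevelHierarchy,
    flatten,
    make_annotation,
    make_conditions,
)


def chain_graph(n: int, root: str = "root") -> AnnotationGraph:
    """T{n} -> ... -> T1 -> root as an AnnotationGraph."""
    g = nx.DiGraph()
    nodes = [f"T{i}" for i in range(1, n + 1)]
    g.add_edge(nodes[0], root, relation="is_a")
    for child, parent in zip(nodes[1:], nodes):
        g.add_edge(child, parent, relation="is_a")
    return AnnotationGraph(root=root, graph=g)


@pytest.fixture
def small_hierarchy() -> ThreeLevelHierarchy:
    """Two level-1 areas, three level-2 categories, four leaf terms."""
    memberships = OrderedDict(
        [
            ("A", {("A", "A")}),
            ("B", {("B", "B")}),
            ("A1", {("A", "A1")}),
            ("A2", {("A", "A2")}),
            ("B1", {("B", "B1")}),
            ("t1", {("A", "A1")}),
            ("t2", {("A", "A1")}),
            ("t3", {("A", "A2")}),
            ("t4", {("B", "B1")}),
        ]
    )
    return ThreeLevelHierarchy(root_label="ROOT", memberships=memberships)


@pytest.fixture
def two_term_annotation() -> GeneAnnotation:
    """Two disjoint equal-size terms; universe is their union."""
    ta = frozenset(f"a{i}" for i in range(5))
    tb = frozenset(f"b{i}" for i in range(5))
    return GeneAnnotation({"TA": ta, "TB": tb}, ta | tb)


@pytest.fixture
def planted_setup():
    spec = FixtureSpec(seed=11)
    graph, ann = make_annotation(spec)
    cs, truth = make_conditions(spec, ann)
    return spec, graph, ann, cs, truth


@pytest.fixture
def mod_condition() -> Condition:
    return Condition(
        id="S1",
        group="G1",
        genes=["g1", "g2", "g3"],
        modifications={"g1": -1.0, "g2": 5.0, "g3": 2.0},
    )
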