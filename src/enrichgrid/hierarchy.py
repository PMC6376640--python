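"""Flattening of rooted annotation DAGs into uniform three-level hierarchies.

GO and Reactome organise their terms in rooted directed acyclic graphs of
arbitrary, non-uniform depth, while KEGG's BRITE classification is natively
three levels deep (general area -> sub-area -> pathway).  To compare and
summarise enrichment results uniformly, every annotation source is projected
onto the BRITE shape: a term keeps its two top-most ancestors on each of its
root-ward paths and is attached directly beneath the depth-2 ancestor.

Conventions used throughout this module:

* An :class:`AnnotationGraph` stores child -> parent edges, so a "path to the
  root" follows edge direction.
* Depth of a node is the number of edges on a shortest path to the root along
  the considered path; the flattening rule is applied per path, so a node
  reachable at several depths collects one membership pair per path family.
* A depth-1 node (direct child of the root) doubles as a level-1 category and
  as a term with the self-referential membership ``(self, self)``; a depth-2
  node gets ``(parent, self)``.  This keeps every annotated term addressable
  at all three display levels.
"""

from __future__ import annotations

import io
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, TextIO

import networkx as nx
import obonet

from .errors import CycleError, DomainError, FormatError, MissingRootError, ParseError

__all__ = [
    "AnnotationGraph",
    "ThreeLevelHierarchy",
    "DepthProfile",
    "parse_obo",
    "parse_kegg_hierarchy",
    "parse_reactome_relations",
    "flatten",
    "depth_profile",
]

#: OBO relationship types retained when restricting the ontology graph.
RETAINED_RELATIONS = frozenset({"is_a", "part_of"})

REACTOME_SUPER_ROOT = "Reactome"


@dataclass
class AnnotationGraph:
    """A rooted DAG of annotation terms with child -> parent edges.

    Parameters
    ----------
    root:
        Identifier of the root category (e.g. ``GO:0008150`` for BP).
    graph:
        ``networkx.DiGraph`` whose edges point from child term to parent
        term; each edge carries a ``relation`` attribute and each node may
        carry a ``name`` attribute.
    """

    root: str
    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if self.root not in self.graph:
            raise MissingRootError(f"root {self.root!r} not in graph")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise CycleError([u for u, _ in cycle] + [cycle[-1][1]])
        if self.graph.out_degree(self.root) != 0:
            raise DomainError(f"root {self.root!r} has an outgoing edge")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def name_of(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def names(self) -> dict[str, str]:
        return {t: self.name_of(t) for t in self.graph.nodes}

    def reachable_terms(self) -> set[str]:
        """Nodes (excluding the root) that have a directed path to the root."""
        return set(nx.ancestors(self.graph, self.root))

    def max_depth(self) -> int:
        """Length of the longest directed path ending at the root."""
        longest = 0
        order = list(nx.topological_sort(self.graph))
        dist = {n: 0 for n in order}
        # edges point child->parent, so walk nodes in topological order and
        # relax toward the root
        for n in reversed(order):
            for child in self.graph.predecessors(n):
                dist[child] = max(dist[child], dist[n] + 1)
        reachable = self.reachable_terms()
        for n, d in dist.items():
            if n in reachable:
                longest = max(longest, d)
        return longest


@dataclass
class ThreeLevelHierarchy:
    """Term memberships in a uniform three-level hierarchy.

    ``memberships`` maps each term to the set of ``(level1, level2)``
    category pairs under which it appears; a term reachable through several
    branches holds one pair per branch.  ``names`` maps identifiers to
    display names for rendering and export.
    """

    root_label: str
    memberships: "OrderedDict[str, set[tuple[str, str]]]" = field(
        default_factory=OrderedDict
    )
    names: dict[str, str] = field(default_factory=dict)

    def name_of(self, ident: str) -> str:
        return self.names.get(ident, ident)

    @property
    def terms(self) -> list[str]:
        return list(self.memberships)

    def level1_categories(self) -> list[str]:
        """Distinct level-1 categories in first-appearance order."""
        seen: OrderedDict[str, None] = OrderedDict()
        for pairs in self.memberships.values():
            for l1, _ in sorted(pairs):
                seen.setdefault(l1)
        return list(seen)

    def level2_categories(self) -> list[str]:
        """Distinct level-2 categories grouped under their level-1 parent."""
        by_parent = self.level2_by_parent()
        out: list[str] = []
        seen: set[str] = set()
        for cats in by_parent.values():
            for c in cats:
                if c not in seen:
                    seen.add(c)
                    out.append(c)
        return out

    def level2_by_parent(self) -> "OrderedDict[str, list[str]]":
        """Level-2 categories listed beneath each level-1 parent."""
        out: OrderedDict[str, list[str]] = OrderedDict()
        for l1 in self.level1_categories():
            out[l1] = []
        for pairs in self.memberships.values():
            for l1, l2 in sorted(pairs):
                if l2 not in out[l1]:
                    out[l1].append(l2)
        return out

    def categories(self, level: int) -> list[str]:
        if level == 1:
            return self.level1_categories()
        if level == 2:
            return self.level2_categories()
        raise DomainError(f"level must be 1 or 2, got {level}")

    def to_tsv(self, stream: TextIO) -> None:
        """Export as 4-column TSV: term, level2, level1, root."""
        for term, pairs in self.memberships.items():
            for l1, l2 in sorted(pairs):
                stream.write(f"{term}\t{l2}\t{l1}\t{self.root_label}\n")

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "ThreeLevelHierarchy":
        memberships: OrderedDict[str, set[tuple[str, str]]] = OrderedDict()
        root_label = ""
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError("expected 4 tab-separated columns", line=lineno)
            term, l2, l1, root_label = parts
            memberships.setdefault(term, set()).add((l1, l2))
        return cls(root_label=root_label, memberships=memberships)


class DepthProfile(NamedTuple):
    n_level1: int
    n_level2: int
    n_terms: int
    max_path_len: int


def _prevalidate_obo(text: str) -> None:
    """Cheap structural check so malformed stanzas report a line number."""
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ParseError("unterminated stanza header", line=lineno)
            in_stanza = True
            continue
        if ":" not in line:
            where = "stanza" if in_stanza else "header"
            raise ParseError(f"{where} line lacks 'tag: value' form", line=lineno)


def parse_obo(stream: TextIO | str, category_root: str) -> AnnotationGraph:
    """Parse an OBO ontology and restrict it to one rooted category.

    Only ``is_a`` and ``part_of`` relationships are retained; every other
    relationship type (``regulates`` etc.) is dropped.  Obsolete terms are
    excluded.  The returned graph contains ``category_root`` plus every term
    with a directed is_a/part_of path to it.

    Parameters
    ----------
    stream:
        OBO 1.2 text or a text stream.
    category_root:
        Term id of the category root (e.g. the BP/CC/MF root term).

    Raises
    ------
    ParseError
        If the OBO text is structurally malformed (with a line number).
    MissingRootError
        If ``category_root`` is absent after parsing.
    """
    text = stream if isinstance(stream, str) else stream.read()
    _prevalidate_obo(text)
    try:
        multi = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    except Exception as exc:  # obonet raises bare ValueError on bad content
        raise ParseError(f"obo parse failed: {exc}") from exc

    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node))
    for child, parent, key in multi.edges(keys=True):
        if key in RETAINED_RELATIONS:
            g.add_edge(child, parent, relation=key)

    if category_root not in g:
        raise MissingRootError(f"category root {category_root!r} not found in OBO")

    keep = nx.ancestors(g, category_root) | {category_root}
    sub = g.subgraph(keep).copy()
    # the category root must not point further up (e.g. at an all-GO root)
    for parent in list(sub.successors(category_root)):
        sub.remove_edge(category_root, parent)
    return AnnotationGraph(root=category_root, graph=sub)


def parse_kegg_hierarchy(stream: TextIO | str) -> ThreeLevelHierarchy:
    """Parse a natively three-level classification (BRITE shape).

    Two dialects are accepted:

    * 3-column TSV: ``level1<TAB>level2<TAB>pathway``;
    * '#'-indented text: ``#`` heading opens a level-1 area, ``##`` a level-2
      sub-area, and any other non-empty line names a pathway beneath the
      current pair of headings.

    A pathway listed under two branches receives both membership pairs.
    """
    text = stream if isinstance(stream, str) else stream.read()
    memberships: OrderedDict[str, set[tuple[str, str]]] = OrderedDict()
    indented = any(
        line.lstrip().startswith("#") for line in text.splitlines() if line.strip()
    )
    if indented:
        level1 = level2 = None
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if level1 is None:
                    raise FormatError("level-2 heading before any level-1", line=lineno)
                level2 = line[2:].strip()
            elif line.startswith("#"):
                level1 = line[1:].strip()
                level2 = None
            else:
                if level1 is None or level2 is None:
                    raise FormatError("pathway record with missing level", line=lineno)
                memberships.setdefault(line, set()).add((level1, level2))
    else:
        for lineno, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                raise FormatError("expected level1, level2, pathway columns", line=lineno)
            l1, l2, pathway = (p.strip() for p in parts)
            memberships.setdefault(pathway, set()).add((l1, l2))

    if not memberships:
        warnings.warn("empty hierarchy stream", stacklevel=2)
    return ThreeLevelHierarchy(root_label="KEGG", memberships=memberships)


def parse_reactome_relations(
    stream: TextIO | str, names: Mapping[str, str] | None = None
) -> AnnotationGraph:
    """Build a rooted graph from pathway parent-child relations.

    Input is a 2-column TSV ``child-id<TAB>parent-id``.  Reactome has a
    forest of top-level pathways; a synthetic super-root labelled
    ``"Reactome"`` is added with every in-degree-0 pathway as its child so
    the forest becomes one rooted DAG.

    Raises
    ------
    CycleError
        If the relations contain a directed cycle (one witness is listed).
    """
    text = stream if isinstance(stream, str) else stream.read()
    g = nx.DiGraph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 2 or not all(p.strip() for p in parts):
            raise FormatError("expected child-id, parent-id columns", line=lineno)
        child, parent = (p.strip() for p in parts)
        g.add_edge(child, parent, relation="child_of")

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError([u for u, _ in cycle] + [cycle[-1][1]])

    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if REACTOME_SUPER_ROOT in g:
        raise FormatError(f"reserved id {REACTOME_SUPER_ROOT!r} present in input")
    g.add_node(REACTOME_SUPER_ROOT, name=REACTOME_SUPER_ROOT)
    for r in roots:
        g.add_edge(r, REACTOME_SUPER_ROOT, relation="child_of")
    names = names or {}
    for node in g.nodes:
        g.nodes[node]["name"] = names.get(node, node)
    return AnnotationGraph(root=REACTOME_SUPER_ROOT, graph=g)


def flatten(graph: AnnotationGraph, max_depth: int = 3) -> ThreeLevelHierarchy:
    """Project a rooted DAG onto the uniform three-level hierarchy.

    For every root-ward path ``t -> ... -> a2 -> a1 -> root`` the term ``t``
    receives the membership pair ``(a1, a2)``: deep terms are re-attached
    directly beneath their depth-2 ancestor on that path.  Depth-1 nodes get
    ``(self, self)`` and depth-2 nodes ``(parent, self)``.  Memberships are
    de-duplicated sets, so multiple paths into the same branch contribute a
    single pair.

    Nodes without any path to the root are skipped with a warning.
    """
    if max_depth != 3:
        raise DomainError("only the three-level projection is supported")
    g = graph.graph
    root = graph.root
    reachable = nx.ancestors(g, root)
    unreachable = set(g.nodes) - reachable - {root}
    if unreachable:
        warnings.warn(
            f"{len(unreachable)} node(s) unreachable from root; skipped",
            stacklevel=2,
        )

    memberships: OrderedDict[str, set[tuple[str, str]]] = OrderedDict()
    for t in g.nodes:  # insertion order = source order
        if t in reachable:
            memberships[t] = set()

    for a1 in g.predecessors(root):
        memberships[a1].add((a1, a1))
        for a2 in g.predecessors(a1):
            pair = (a1, a2)
            memberships[a2].add(pair)
            for t in nx.ancestors(g, a2):
                memberships[t].add(pair)

    return ThreeLevelHierarchy(
        root_label=graph.name_of(root),
        memberships=memberships,
        names=graph.names(),
    )


def depth_profile(h: ThreeLevelHierarchy) -> DepthProfile:
    """Category/term counts and the longest term -> root path length.

    In the induced display graph a term with pair ``(l1, l2)`` sits at the
    end of the path ``term -> l2 -> l1 -> root`` (3 edges); a depth-2 term
    (``term == l2``) contributes 2 edges and a level-1 category 1 edge.
    """
    level1: set[str] = set()
    level2: set[str] = set()
    max_len = 0
    for term, pairs in h.memberships.items():
        for l1, l2 in pairs:
            level1.add(l1)
            level2.add(l2)
            if term == l1 == l2:
                max_len = max(max_len, 1)
            elif term == l2:
                max_len = max(max_len, 2)
            else:
                max_len = max(max_len, 3)
    return DepthProfile(len(level1), len(level2), len(h.memberships), max_len)
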