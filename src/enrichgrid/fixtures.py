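"""Synthetic annotation graphs and condition sets with planted structure.

The generator builds the whole test bed without any database download:

* a rooted annotation DAG with a regular three-level core (level-1 areas,
  level-2 sub-areas, leaf terms) plus optional deeper chains hanging below
  chosen terms, so flattening is actually exercised;
* a gene universe with term gene sets drawn uniformly at random;
* experimental conditions organised in groups, each group drawing a fixed
  fraction of its genes from the terms of its *planted* level-2 categories
  and the rest uniformly from the universe, with modification values equal
  to a group-signed effect plus Gaussian noise.

Defaults mirror the scale of a typical multi-exposure transcriptomics
screen: 60 genes per condition (e.g. the 30 most up- and 30 most
down-regulated genes of a comparison), a universe of 2000 annotated genes,
20 genes per term, and 6 conditions in 2 groups.

Everything is reproducible from ``FixtureSpec.seed``; the returned truth
record is sufficient to score recovery of the planted categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TextIO

import networkx as nx
import numpy as np

from .enrichment import Condition, ConditionSet, GeneAnnotation
from .errors import DomainError
from .hierarchy import AnnotationGraph

__all__ = [
    "FixtureSpec",
    "make_annotation",
    "make_conditions",
    "write_obo",
    "write_annotation_tsv",
]

ROOT = "ROOT"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    ``planted_fraction`` is the proportion of each condition's gene list
    drawn from its group's planted level-2 categories; ``modification_effect``
    is the mean modification value of all genes in a condition, with sign
    alternating by group (+ for even-indexed groups, - for odd).
    """

    n_level1: int = 3
    n_level2_per: int = 2
    n_terms_per: int = 3
    extra_depth_chains: int = 2
    chain_length: int = 2
    genes_per_term: int = 20
    universe_size: int = 2000
    genes_per_condition: int = 60
    n_conditions: int = 6
    n_groups: int = 2
    planted_categories_per_group: int = 1
    planted_fraction: float = 0.7
    modification_effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_level1": self.n_level1,
            "n_level2_per": self.n_level2_per,
            "n_terms_per": self.n_terms_per,
            "genes_per_term": self.genes_per_term,
            "universe_size": self.universe_size,
            "genes_per_condition": self.genes_per_condition,
            "n_conditions": self.n_conditions,
            "n_groups": self.n_groups,
            "planted_categories_per_group": self.planted_categories_per_group,
        }
        for name, v in counts.items():
            if v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")
        if not 0 <= self.planted_fraction <= 1:
            raise DomainError("planted_fraction must lie in [0, 1]")
        if self.genes_per_term > self.universe_size:
            raise DomainError("genes_per_term exceeds universe_size")
        n_l2 = self.n_level1 * self.n_level2_per
        if self.n_groups * self.planted_categories_per_group > n_l2:
            raise DomainError(
                "not enough level-2 categories for disjoint planted sets"
            )
        if self.n_conditions < self.n_groups:
            raise DomainError("need at least one condition per group")

    # --- naming conventions (shared with make_conditions) -----------------
    def level1_ids(self) -> list[str]:
        return [f"L1_{i}" for i in range(1, self.n_level1 + 1)]

    def level2_ids(self) -> list[str]:
        return [
            f"L2_{i}_{j}"
            for i in range(1, self.n_level1 + 1)
            for j in range(1, self.n_level2_per + 1)
        ]

    def terms_of(self, level2: str) -> list[str]:
        _, i, j = level2.split("_")
        return [f"T_{i}_{j}_{k}" for k in range(1, self.n_terms_per + 1)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.universe_size)]

    def planted_level2(self) -> dict[str, list[str]]:
        """Disjoint planted level-2 categories per group label."""
        l2 = self.level2_ids()
        per = self.planted_categories_per_group
        return {
            f"G{g + 1}": l2[g * per : (g + 1) * per] for g in range(self.n_groups)
        }


def make_annotation(spec: FixtureSpec) -> tuple[AnnotationGraph, GeneAnnotation]:
    """Build the fixture DAG and its term -> gene annotation.

    Deep chains (``extra_depth_chains`` of them, each ``chain_length`` nodes)
    are attached below leaf terms, giving root-ward paths of length
    ``3 + chain_length`` so the three-level projection has real work to do.
    Chain nodes are annotated terms like any leaf.
    """
    rng = np.random.default_rng([spec.seed, 0])
    g = nx.DiGraph()
    g.add_node(ROOT, name=ROOT)
    leaf_terms: list[str] = []
    for l1 in spec.level1_ids():
        g.add_edge(l1, ROOT, relation="is_a")
    for l2 in spec.level2_ids():
        l1 = "L1_" + l2.split("_")[1]
        g.add_edge(l2, l1, relation="is_a")
        for t in spec.terms_of(l2):
            g.add_edge(t, l2, relation="is_a")
            leaf_terms.append(t)

    chain_hosts = rng.choice(len(leaf_terms), size=spec.extra_depth_chains, replace=True)
    chain_terms: list[str] = []
    for c, host_idx in enumerate(chain_hosts, start=1):
        parent = leaf_terms[host_idx]
        for step in range(1, spec.chain_length + 1):
            node = f"C_{c}_{step}"
            g.add_edge(node, parent, relation="is_a")
            chain_terms.append(node)
            parent = node

    for node in g.nodes:
        g.nodes[node].setdefault("name", node)

    genes = np.array(spec.gene_ids())
    term_to_genes = {}
    for term in leaf_terms + chain_terms:
        picked = rng.choice(spec.universe_size, size=spec.genes_per_term, replace=False)
        term_to_genes[term] = frozenset(genes[np.sort(picked)])
    ann = GeneAnnotation(term_to_genes=term_to_genes, universe=frozenset(genes))
    return AnnotationGraph(root=ROOT, graph=g), ann


def make_conditions(
    spec: FixtureSpec, ann: GeneAnnotation
) -> tuple[ConditionSet, dict]:
    """Generate grouped conditions with planted enrichment and its truth.

    Conditions ``S1..Sn`` are assigned to groups round-robin.  Each draws
    ``planted_fraction`` of its genes (without replacement) from the union
    of its group's planted terms' gene sets and the remainder uniformly from
    the rest of the universe.  Modifications are
    ``sign(group) * modification_effect + N(0, noise_sd)``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    planted = spec.planted_level2()
    planted_terms = {
        grp: [t for l2 in cats for t in spec.terms_of(l2)]
        for grp, cats in planted.items()
    }
    universe = np.array(sorted(ann.universe))
    conditions: list[Condition] = []
    for c in range(spec.n_conditions):
        gidx = c % spec.n_groups
        group = f"G{gidx + 1}"
        pool = sorted(set().union(*(ann.term_to_genes[t] for t in planted_terms[group])))
        n_planted = round(spec.planted_fraction * spec.genes_per_condition)
        if n_planted > len(pool):
            warnings.warn(
                f"planted pool ({len(pool)}) smaller than requested draw "
                f"({n_planted}); drawing the whole pool",
                stacklevel=2,
            )
            n_planted = len(pool)
        chosen = list(rng.choice(pool, size=n_planted, replace=False)) if n_planted else []
        background_pool = np.array([g for g in universe if g not in set(chosen)])
        n_bg = spec.genes_per_condition - n_planted
        chosen += list(rng.choice(background_pool, size=n_bg, replace=False))
        sign = 1.0 if gidx % 2 == 0 else -1.0
        mods = {
            g: float(sign * spec.modification_effect + rng.normal(0, spec.noise_sd))
            for g in chosen
        }
        conditions.append(
            Condition(id=f"S{c + 1}", group=group, genes=chosen, modifications=mods)
        )
    truth = {
        "condition_groups": {c.id: c.group for c in conditions},
        "planted_level2": planted,
        "planted_terms": planted_terms,
    }
    return ConditionSet(conditions), truth


def write_obo(graph: AnnotationGraph, stream: TextIO) -> None:
    """Serialise an AnnotationGraph as minimal OBO 1.2 text (is_a edges)."""
    stream.write("format-version: 1.2\nontology: synthetic-fixture\n")
    for node in graph.graph.nodes:
        stream.write(f"\n[Term]\nid: {node}\nname: {graph.name_of(node)}\n")
        for parent in graph.graph.successors(node):
            rel = graph.graph.edges[node, parent].get("relation", "is_a")
            if rel == "is_a":
                stream.write(f"is_a: {parent} ! {graph.name_of(parent)}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")


def write_annotation_tsv(ann: GeneAnnotation, stream: TextIO) -> None:
    """Serialise term -> gene pairs as 2-column TSV."""
    for term in ann.terms:
        for gene in sorted(ann.term_to_genes[term]):
            stream.write(f"{term}\t{gene}\n")
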