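"""Flatten an arbitrary-depth annotation DAG onto three levels.

Builds a small ontology-style graph containing a five-deep chain and a
diamond, flattens it, and prints each term's (level-1, level-2) memberships.
A deep term is re-attached directly beneath its depth-2 ancestor, so every
term ends up at most three edges from the root.
"""

import networkx as nx

from enrichgrid import AnnotationGraph, depth_profile, flatten

g = nx.DiGraph()
edges = [
    ("metabolism", "root"),
    ("lipid metabolism", "metabolism"),
    ("fatty acid degradation", "lipid metabolism"),
    ("beta oxidation", "fatty acid degradation"),          # depth 4
    ("acyl-CoA handling", "beta oxidation"),               # depth 5
    ("signaling", "root"),
    ("lipid signaling", "signaling"),
    ("sphingolipid pathway", "lipid signaling"),
    ("sphingolipid pathway", "lipid metabolism"),          # diamond: two branches
]
for child, parent in edges:
    g.add_edge(child, parent, relation="is_a")

graph = AnnotationGraph(root="root", graph=g)
h = flatten(graph)

print(f"source graph depth: {graph.max_depth()}")
prof = depth_profile(h)
print(
    f"flattened: {prof.n_terms} terms, {prof.n_level1} level-1 / "
    f"{prof.n_level2} level-2 categories, max path length {prof.max_path_len}"
)
for term, pairs in h.memberships.items():
    for l1, l2 in sorted(pairs):
        print(f"  {term:24s} -> level1={l1:12s} level2={l2}")
# 'acyl-CoA handling' sits 5 edges deep in the source but lands under
# (metabolism, lipid metabolism); the diamond term keeps both branch pairs.
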