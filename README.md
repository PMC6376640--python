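# enrichgrid

Comparing the functional profile of many omics experiments at once is hard:
each gene list yields dozens to hundreds of enriched GO terms or pathways,
and collating separate enrichment runs by hand quickly becomes unreadable.
`enrichgrid` is a library (with a thin command-line front end) for analysts
who face exactly that: it organises enrichment results from **multiple
experimental conditions** into a **uniform three-level functional
hierarchy**, summarises them upward, clusters the conditions by profile
similarity, and renders everything as one annotated grid map.

## The method

**Three-level flattening.** KEGG's BRITE classification is natively three
levels deep (area → sub-area → pathway); GO and Reactome are rooted DAGs of
arbitrary, non-uniform depth. `enrichgrid` projects every annotation source
onto the BRITE shape: restricting GO to `is_a`/`part_of` edges gives an
acyclic graph rooted at the category root, and for every root-ward path
`t → … → a₂ → a₁ → root` the term `t` is re-attached directly beneath its
depth-2 ancestor, receiving the membership pair `(a₁, a₂)`. Depth-1 nodes
become level-1 categories with membership `(self, self)`; depth-2 nodes get
`(parent, self)`. Multiple paths yield multiple pairs (set semantics). The
result: every annotated term is at most three edges from the root.

**Per-condition ORA.** Each condition is a gene list (optionally with
per-gene modification values such as fold changes or t-statistics). A term
with overlap `x` against a query of size `n` from a universe of `N` genes
(`K` of them in the term) is scored with the upper-tail hypergeometric
probability

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ x), X ~ Hypergeom(N, K, n),

corrected across the tested terms by Bonferroni or Benjamini–Hochberg and
filtered at a significance threshold α.

**Matrices and summarisation.** Enrichment results form the matrix
`Ter[N×M]` (conditions × enriched terms); a cell holds the adjusted
p-value, the summarised modification value MV (min/median/mean/max over the
overlapping genes), or the combination `MV × −log₁₀(p)`. Level matrices
`Ter_i[N×K]` (i = 1, 2) apply the summary statistic over each category's
defined descendant-term cells, always computed from the term matrix
directly. A sign display reduces signed cells to {−1, 0, +1}.

**Condition clustering.** Three distances over enrichment profiles:
Jaccard `D = 1 − |Terms(k)∩Terms(l)| / |Terms(k)∪Terms(l)|`; the Euclidean
distance `DE` over the cells of terms enriched in *both* conditions (pairs
sharing none are maximally dissimilar); and the combination
`M = (D + DE₀₁)/2` with `DE₀₁` min-max scaled to [0, 1]. Agglomerative
clustering (complete, single, or Ward linkage) on the chosen matrix
reorders the map columns and cuts into k groups.

A built-in synthetic-data generator (`FixtureSpec`, `make_annotation`,
`make_conditions`) produces annotation DAGs with deeper-than-three chains,
gene universes, and grouped conditions with planted enrichment — the whole
pipeline is testable offline.

## Worked example

```sh
python examples/summarize_and_cluster.py
```

```
term matrix: 6 conditions x 8 enriched terms
level-2 matrix columns: ['L2_1_1', 'L2_1_2', 'L2_2_2', 'L2_3_2']
    L2_1_1  L2_1_2  L2_2_2  L2_3_2
S1     0.0     NaN     NaN     NaN
S2     NaN     0.0     NaN  0.0093
S3     0.0     NaN  0.0488  0.0488
S4     NaN     0.0     NaN     NaN
S5     0.0     NaN     NaN     NaN
S6     NaN     0.0     NaN     NaN

cluster labels (k=2): {'S1': 2, 'S2': 1, 'S3': 2, 'S4': 1, 'S5': 2, 'S6': 1}
true groups:          {'S1': 'G1', 'S2': 'G2', 'S3': 'G1', 'S4': 'G2', 'S5': 'G1', 'S6': 'G2'}
dendrogram: ((S2:0.25,(S4:0,S6:0):0.25):0.75,(S3:0.4,(S1:0,S5:0):0.4):0.6);
```

Six synthetic conditions in two groups each planted one level-2 category:
the odd-numbered conditions enrich `L2_1_1` (median adjusted p ≈ 10⁻¹⁴,
displayed as 0.0), the even-numbered ones `L2_1_2`; NaN means "no enriched
descendant". The Jaccard distance between the groups' enriched-term sets is
near 1, so the k = 2 cut of the complete-linkage tree reproduces the
planted grouping exactly. The other scripts in `examples/` show hierarchy
flattening, per-condition ORA, and the full file-based pipeline
(`run_pipeline` → TSVs, Newick dendrogram, SVG grid map).

The same pipeline is scriptable from the shell:

```sh
enrichgrid run --workbook conditions.xlsx --annotation term2gene.tsv \
    --hierarchy-source go-basic.obo --kind go-bp --root GO:0008150 \
    --level 2 --k 4 --out-dir results/
```

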