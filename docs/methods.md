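# Methods

## The three-level projection

Annotation sources are modelled as rooted DAGs with child → parent edges
(`AnnotationGraph`). For GO-style input only `is_a` and `part_of`
relationships are retained (all others are dropped with a debug log line),
obsolete terms are excluded, and the graph is restricted to nodes with a
path to the chosen category root. Reactome-style parent–child relations are
a forest of top-level pathways; a synthetic super-root labelled `Reactome`
adopts every in-degree-0 pathway so one rooted graph results. KEGG-style
input is already three levels deep and parses straight into memberships.

Flattening attaches every term beneath the two top-most ancestors of each
of its root-ward paths: a path `t → … → a₂ → a₁ → root` contributes the
membership pair `(a₁, a₂)`. The implementation does not enumerate paths; it
iterates over the root's children `a₁` and their children `a₂` and assigns
`(a₁, a₂)` to `a₂` and all of its graph descendants, which is equivalent
(a path through `a₂, a₁` exists exactly when the term descends from `a₂`)
and linear-ish in practice. Design choices made where the projection rule
is under-determined:

* **Depth-1 and depth-2 nodes.** A direct child of the root is both a
  level-1 category and a term with membership `(self, self)`; a depth-2
  node gets `(parent, self)`. This keeps every annotated term addressable
  at all three display levels.
* **Multiple paths.** Every branch contributes a pair; memberships are
  de-duplicated sets, no primary-path election. Summarisation tolerates
  multi-membership naturally, so there is no reason to break ties.
* **Reactome.** Treated identically to GO after super-root insertion:
  level 1 = top-level pathways, level 2 = their direct children, deeper
  pathways attach beneath their depth-2 ancestor.
* **Cycles.** A cycle among retained relations aborts with an error that
  names one offending cycle; corrupt input should be loud, not silently
  repaired by edge dropping.
* Only the three-level projection is implemented; `flatten(max_depth=...)`
  rejects anything else rather than pretending to generalise.

## Over-representation analysis

A term with gene set of size K is scored against a query of size n from a
universe of N genes by the upper-tail hypergeometric probability
P(X ≥ x) (scipy's survival function). Only terms with overlap ≥ 1 are
tested, and the multiple-testing correction (Bonferroni or
Benjamini–Hochberg via statsmodels) spans exactly those terms. Records are
kept when adjusted p ≤ α (inclusive). The default universe is the set of
genes annotated to at least one term of the chosen annotation; an explicit
universe file overrides it. Gene matching is exact-string after an optional
alias → canonical mapping table; species handling is therefore data, not
code. The gSCS correction of g:Profiler is not implemented (its internals
are unpublished); the interfaces accept `bonferroni` and `fdr` only.

Modification values (fold changes, t-statistics — unitless as far as the
pipeline is concerned) are summarised per enriched term by min / median /
mean / max over the genes in the overlap. Cell values for the matrices are
the adjusted p, the MV summary, or `MV × −log₁₀(adjusted p)`; base 10 is
the conventional choice for enrichment displays.

## Matrices and summarisation

`Ter[N×M]` holds one row per condition and one column per term enriched in
at least one condition; a cell is defined only where that term is enriched
in that condition (NaN otherwise — a non-enriched cell is *unknown*, not
zero, so undefined cells never enter any statistic). Level matrices are
always computed from the term matrix directly, never by chaining level 2 →
level 1: the median of medians is not the median (min and max would
commute, and a test asserts exactly that associativity and nothing more).
A term with several memberships contributes to every category it belongs
to, once per category. Columns are ordered by the hierarchy: level-1
categories in source order, level-2 categories grouped beneath their
parent, term columns sorted by id. Enriched terms missing from the
hierarchy are collected under an `unmapped` category with a warning.

## Distances and clustering

* **Jaccard**: 1 − |∩|/|∪| over enriched-term sets; a pair of conditions
  that are both empty is identical (distance 0).
* **Euclidean on common terms**: per pair, over the cells of terms
  enriched in both conditions. A pair with *no* shared term receives the
  maximum finite distance in the matrix — no shared enriched term is the
  strongest dissimilarity signal available. If no pair shares a term the
  matrix degenerates to all-1 off-diagonal with a warning. Because every
  pair uses its own subvector this is not a metric; nothing downstream
  assumes the triangle inequality.
* **Combined**: (D + DE₀₁)/2, where DE₀₁ is the Euclidean matrix min-max
  scaled over its off-diagonal entries (a constant matrix scales to 0).
* The matrix fed to the distance is the term-level matrix by default
  (`distance_level=3`); level 1 or 2 may be selected instead, since which
  level the profile distance should read from is a display-level choice.

Clustering is scipy agglomerative linkage on the precomputed condensed
matrix; `ward` follows the Ward-on-dissimilarity convention
(Lance–Williams update on squared distances of the supplied matrix).
Results are deterministic for a given input because scipy's algorithm is;
exact ties are resolved by scipy's merge order. `cut_clusters` relabels
scipy's `cut_tree` output 1..k in dendrogram leaf order.

## Synthetic study conditions

The generator emulates a multi-exposure transcriptomics screen:

| parameter | default | why |
| --- | --- | --- |
| universe size | 2000 genes | small genome-scale annotation at desk scale |
| genes per term | 20 | typical pathway-sized gene set |
| genes per condition | 60 | the 30 most up- + 30 most down-regulated genes of a comparison |
| conditions / groups | 6 / 2 | smallest layout where group recovery is non-trivial |
| planted fraction | 0.7 | strong but not degenerate enrichment signal |
| modification effect ± sd | ±2.0, 0.5 | clear group-signed effect with overlapping noise |
| hierarchy core | 3×2×3 terms + 2 chains of 2 | exercises flattening (depth 5) without bloat |

Each group plants one (disjoint) level-2 category; a condition draws 70% of
its genes uniformly without replacement from the planted terms' gene pool
and the rest uniformly from the remaining universe. Modifications are
group-signed Gaussians. Everything is reproducible from `FixtureSpec.seed`
(numpy `default_rng` with spawn-style sub-seeds), and the returned truth
record scores recovery.

What the generator does **not** emulate: real GO/KEGG topology statistics,
correlated term gene sets, expression-dependent gene selection, or
annotation bias. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generative model — not
performance on any real annotation corpus.

## Calibration of the null

Term tests are discrete: with terms of 20 genes, queries of 60 and a
universe of 2000, the attained level of the rule "raw p ≤ 0.05" is ≈ 0.02,
not 0.05 (the achievable p-values jump past the nominal level). The null
calibration check therefore compares the observed rejection fraction over
200 replicated null studies against its *exact expectation* — the per-term
attained level computed from the hypergeometric null by combinatorial
summation — within the exact binomial 99% interval. Comparing against the
nominal 0.05 would mistake conservatism for miscalibration.

## Numerical and testing choices

* Hypergeometric tail, BH step-up, flattening, and clustering each have an
  independent oracle in the test suite (combinatorial sums, a hand-rolled
  step-up, brute-force `all_simple_paths` enumeration, a literal O(N³)
  Lance–Williams agglomeration). Merge trees are compared as sets of
  (leaf-set, height) internal nodes, which is invariant to the order in
  which equivalent merges are emitted.
* Problem sizes in the test and acceptance runs — ≤200-node random DAGs
  (50 graphs), universes ≤ 12 for the exhaustive sweep, 100–200 replicates
  for recovery and calibration — were chosen so that brute-force oracles
  stay exact while the whole suite completes in well under a minute.
* TSV exports render floats with `%.10g`-style formatting and empty
  strings for undefined cells; two runs of the pipeline on identical
  inputs produce byte-identical TSV/Newick artifacts.
* SVG output is written with a cleared Date metadata field so map files
  are reproducible too.

## Known limitations

* One annotation source per run; no cross-source term de-duplication.
* No GSEA-style ranked statistics and no topology-aware GO decorrelation
  (elim/weight); terms are tested independently.
* No live database retrieval, OWL parsing, or ortholog/ID conversion
  beyond the user-supplied alias table.
* `euclidean_common` distances are comparable within one matrix only;
  their absolute scale depends on the value mode.
* No bootstrap/consensus clustering and no automatic choice of k; the
  dendrogram is exported so users can judge k themselves.
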