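"""End-to-end pipeline: workbook -> enrichment -> matrices -> map.

``run_pipeline`` drives the whole analysis from a :class:`RunConfig` and
writes every intermediate artifact (TSVs, Newick, SVG, log) into the output
directory, so interactive re-exploration (changing level, filters, k) only
needs the cheap tail of the computation.  The run is deterministic given
its inputs and seed.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import hierarchy as hmod
from .clustering import (
    combined_distance,
    cut_clusters,
    euclidean_common_distance,
    hierarchical_cluster,
    jaccard_distance,
)
from .enrichment import (
    apply_mapping,
    enrich,
    read_gene_annotation,
    read_mapping,
    write_enrichment_tsv,
)
from .errors import DomainError, EnrichGridError, InputError
from .grid import render_grid
from .matrices import apply_sign_mode, build_term_matrix, filter_view, summarize_to_level, term_sets
from .workbook import read_workbook

__all__ = ["RunConfig", "run_pipeline", "load_hierarchy", "PipelineError"]

logger = logging.getLogger(__name__)

ANNOTATION_KINDS = ("go-bp", "go-cc", "go-mf", "kegg", "reactome")
DISTANCE_KINDS = ("jaccard", "euclidean", "combined")


class PipelineError(EnrichGridError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``annotation_root`` is the category-root term id and is required for the
    GO kinds (the OBO file may contain several categories); KEGG and
    Reactome inputs define their own root.
    """

    workbook: Path
    gene_annotation: Path
    hierarchy_source: Path
    annotation_kind: str = "kegg"
    annotation_root: str | None = None
    reactome_names: Path | None = None
    mapping: Path | None = None
    universe: Path | None = None
    stat: str = "median"
    method: str = "fdr"
    alpha: float = 0.05
    mode: str = "enrichment_p"
    sign: bool = False
    level: int = 3
    distance: str = "jaccard"
    distance_level: int = 3
    linkage: str = "complete"
    k: int | None = None
    keep_categories: dict[int, list[str]] | None = None
    keep_conditions: list[str] | None = None
    out_dir: Path = Path("enrichgrid_out")
    seed: int = 0

    def __post_init__(self) -> None:
        self.workbook = Path(self.workbook)
        self.gene_annotation = Path(self.gene_annotation)
        self.hierarchy_source = Path(self.hierarchy_source)
        self.out_dir = Path(self.out_dir)
        self.annotation_kind = self.annotation_kind.lower()
        if self.annotation_kind not in ANNOTATION_KINDS:
            raise DomainError(
                f"annotation kind must be one of {ANNOTATION_KINDS}, "
                f"got {self.annotation_kind!r}"
            )
        if self.annotation_kind.startswith("go-") and not self.annotation_root:
            raise DomainError("GO annotation kinds require annotation_root")
        if not 0 < self.alpha <= 1:
            raise DomainError("alpha must lie in (0, 1]")
        if self.level not in (1, 2, 3):
            raise DomainError("level must be 1, 2 or 3")
        if self.distance_level not in (1, 2, 3):
            raise DomainError("distance_level must be 1, 2 or 3")
        if self.distance not in DISTANCE_KINDS:
            raise DomainError(f"distance must be one of {DISTANCE_KINDS}")
        if self.sign and self.mode == "enrichment_p":
            raise DomainError("sign display requires a modification-carrying mode")


@contextlib.contextmanager
def _stage(name: str, log: list[str]):
    log.append(f"stage {name}: start")
    try:
        yield
    except EnrichGridError as exc:
        log.append(f"stage {name}: FAILED ({exc})")
        raise PipelineError(f"stage {name!r}: {exc}") from exc
    log.append(f"stage {name}: ok")


def load_hierarchy(config: RunConfig) -> hmod.ThreeLevelHierarchy:
    """Build the three-level hierarchy for the configured annotation kind."""
    text = config.hierarchy_source.read_text()
    if config.annotation_kind == "kegg":
        return hmod.parse_kegg_hierarchy(text)
    if config.annotation_kind == "reactome":
        names = None
        if config.reactome_names is not None:
            names = dict(
                line.split("\t")[:2]
                for line in Path(config.reactome_names).read_text().splitlines()
                if line.strip()
            )
        graph = hmod.parse_reactome_relations(text, names=names)
    else:  # go-bp / go-cc / go-mf
        graph = hmod.parse_obo(text, category_root=config.annotation_root)
    return hmod.flatten(graph)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis, writing every artifact under ``out_dir``.

    Returns a name -> path map of the written files.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed {config.seed}"]
    artifacts: dict[str, Path] = {}

    with _stage("hierarchy", log):
        h = load_hierarchy(config)
        p = out / "hierarchy.tsv"
        with open(p, "w") as fh:
            h.to_tsv(fh)
        artifacts["hierarchy"] = p

    with _stage("annotation", log):
        universe = None
        if config.universe is not None:
            universe = [
                g.strip()
                for g in Path(config.universe).read_text().splitlines()
                if g.strip()
            ]
        with open(config.gene_annotation) as fh:
            annotation = read_gene_annotation(fh, universe=universe)

    with _stage("workbook", log):
        cs = read_workbook(config.workbook)
        if config.mapping is not None:
            with open(config.mapping) as fh:
                mapping = read_mapping(fh)
            cs.conditions = [apply_mapping(c, mapping) for c in cs.conditions]
        needs_mods = config.sign or config.mode in ("modification", "combined")
        if needs_mods and not cs.has_modifications():
            raise InputError(
                f"value mode {config.mode!r} needs modification values in every sheet"
            )
        if config.k is not None and not 1 <= config.k <= len(cs):
            raise DomainError(f"k={config.k} outside [1, {len(cs)}]")

    with _stage("enrichment", log):
        results = [
            enrich(c, annotation, alpha=config.alpha, method=config.method,
                   stat=config.stat)
            for c in cs
        ]
        p = out / "enrichment.tsv"
        with open(p, "w") as fh:
            write_enrichment_tsv(results, fh)
        artifacts["enrichment"] = p

    with _stage("term_matrix", log):
        tm = build_term_matrix(results, mode=config.mode)
        p = out / "term_matrix.tsv"
        tm.to_tsv(p)
        artifacts["term_matrix"] = p
        p = out / "term_columns.tsv"
        with open(p, "w") as fh:
            for term in tm.terms:
                for l1, l2 in sorted(h.memberships.get(term, {("unmapped",) * 2})):
                    fh.write(f"{term}\t{l1}\t{l2}\n")
        artifacts["term_columns"] = p

    with _stage("summarize", log):
        display = tm
        if config.level in (1, 2):
            display = summarize_to_level(tm, h, level=config.level, stat=config.stat)
            p = out / f"level{config.level}_matrix.tsv"
            display.to_tsv(p)
            artifacts[f"level{config.level}_matrix"] = p
        if config.keep_categories or config.keep_conditions:
            display = filter_view(
                display, h,
                keep_categories=config.keep_categories,
                keep_conditions=config.keep_conditions,
            )
        if config.sign:
            display = apply_sign_mode(display)
            p = out / "sign_matrix.tsv"
            display.to_tsv(p)
            artifacts["sign_matrix"] = p

    column_order = None
    if len(cs) >= 2:
        with _stage("clustering", log):
            dist_matrix = tm
            if config.distance_level in (1, 2):
                dist_matrix = summarize_to_level(
                    tm, h, level=config.distance_level, stat=config.stat
                )
            sets = term_sets(dist_matrix)
            if config.distance == "jaccard":
                d = jaccard_distance(sets)
            elif config.distance == "euclidean":
                d = euclidean_common_distance(dist_matrix)
            else:
                d = combined_distance(
                    jaccard_distance(sets), euclidean_common_distance(dist_matrix)
                )
            p = out / "distance.tsv"
            d.to_tsv(p)
            artifacts["distance"] = p
            dend = hierarchical_cluster(d, linkage=config.linkage)
            p = out / "dendrogram.nwk"
            p.write_text(dend.to_newick() + "\n")
            artifacts["dendrogram"] = p
            if config.k is not None:
                labels = cut_clusters(dend, config.k)
                p = out / "clusters.tsv"
                with open(p, "w") as fh:
                    for cond in cs.ids:
                        fh.write(f"{cond}\t{labels[cond]}\n")
                artifacts["clusters"] = p
                column_order = dend.leaf_order

    with _stage("render", log):
        fig = render_grid(
            display, h,
            out=out / "map.svg",
            column_order=column_order,
            group_labels=cs.groups,
        )
        if fig is not None:
            artifacts["map"] = out / "map.svg"
            import matplotlib.pyplot as plt

            plt.close(fig)
        else:
            log.append("render: empty map, skipped")

    p = out / "log.txt"
    p.write_text("\n".join(log) + "\n")
    artifacts["log"] = p
    return artifacts
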