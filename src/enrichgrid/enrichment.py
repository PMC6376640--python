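"""Per-condition over-representation analysis (ORA).

Each experimental condition contributes one gene list, optionally with a
per-gene modification value (fold change, t-statistic, ...).  A term is
scored by the upper-tail hypergeometric probability of its overlap with the
list, adjusted for multiple testing with Bonferroni or Benjamini-Hochberg,
and annotated with a summary (min/median/mean/max) of the modification
values of the overlapping genes.

The test universe defaults to all genes annotated to at least one term of
the chosen annotation; pass ``universe`` explicitly to override.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InputError, UnsupportedModeError

__all__ = [
    "GeneAnnotation",
    "Condition",
    "ConditionSet",
    "EnrichmentRecord",
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "adjust_pvalues",
    "enrich",
    "modification_summary",
    "cell_value",
    "read_gene_annotation",
    "read_mapping",
    "apply_mapping",
    "write_enrichment_tsv",
    "read_enrichment_tsv",
]

logger = logging.getLogger(__name__)

SUMMARY_STATS = {
    "min": np.min,
    "median": np.median,
    "mean": np.mean,
    "max": np.max,
}

VALUE_MODES = ("enrichment_p", "modification", "combined")
CORRECTION_METHODS = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}


@dataclass
class GeneAnnotation:
    """Term -> gene-set map plus the test universe."""

    term_to_genes: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()}
        self.universe = frozenset(self.universe)
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise InputError(f"term {term!r} has an empty gene set")
            if not genes <= self.universe:
                missing = sorted(genes - self.universe)[:3]
                raise InputError(
                    f"term {term!r} annotates genes outside the universe: {missing}"
                )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneAnnotation":
        term_to_genes: dict[str, set[str]] = {}
        for term, gene in pairs:
            term_to_genes.setdefault(term, set()).add(gene)
        annotated = set().union(*term_to_genes.values()) if term_to_genes else set()
        uni = set(universe) if universe is not None else annotated
        return cls({t: frozenset(g) for t, g in term_to_genes.items()}, frozenset(uni))

    @property
    def terms(self) -> list[str]:
        return list(self.term_to_genes)


@dataclass
class Condition:
    """One experimental condition: a gene list with optional modifications."""

    id: str
    group: str
    genes: list[str]
    modifications: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})[:3]
            raise InputError(f"condition {self.id!r}: duplicate gene ids {dupes}")
        if self.modifications is not None and set(self.modifications) != set(self.genes):
            raise InputError(
                f"condition {self.id!r}: modification values do not align with genes"
            )


@dataclass
class ConditionSet:
    """Ordered conditions as read from a workbook's groups sheet."""

    conditions: list[Condition]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate condition ids")

    def __iter__(self):
        return iter(self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conditions]

    @property
    def groups(self) -> dict[str, str]:
        return {c.id: c.group for c in self.conditions}

    def has_modifications(self) -> bool:
        present = [c.modifications is not None for c in self.conditions]
        if any(present) and not all(present):
            raise InputError(
                "modification values must be present in all conditions or none"
            )
        return all(present) and bool(present)


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    raw_p: float
    adj_p: float
    overlap: int
    mv_summary: float | None = None


@dataclass
class EnrichmentResult:
    condition_id: str
    records: list[EnrichmentRecord] = field(default_factory=list)

    @property
    def terms(self) -> set[str]:
        return {r.term for r in self.records}

    def record_for(self, term: str) -> EnrichmentRecord:
        for r in self.records:
            if r.term == term:
                return r
        raise KeyError(term)


def hypergeometric_pvalue(
    overlap: int, term_size: int, query_size: int, universe_size: int
) -> float:
    """Upper-tail probability ``P(X >= overlap)`` of the hypergeometric draw.

    ``X`` counts term genes in a uniform draw of ``query_size`` genes from a
    universe of ``universe_size`` containing ``term_size`` term genes.
    """
    if not (0 <= overlap <= min(term_size, query_size)):
        raise DomainError(
            f"overlap {overlap} outside [0, min(term={term_size}, query={query_size})]"
        )
    if term_size > universe_size or query_size > universe_size:
        raise DomainError("term/query size exceeds universe size")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def adjust_pvalues(raw: Sequence[float], method: str = "fdr") -> list[float]:
    """Multiple-testing adjustment, order-preserving.

    ``bonferroni``: ``min(1, m*p)``.  ``fdr``: Benjamini-Hochberg step-up
    with the usual monotonicity enforcement.
    """
    if method not in CORRECTION_METHODS:
        raise DomainError(f"unknown correction method {method!r}")
    raw = list(raw)
    if not raw:
        return []
    arr = np.asarray(raw, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(arr, method=CORRECTION_METHODS[method])[1].tolist()


def modification_summary(
    condition: Condition, term_genes: Iterable[str], stat: str = "median"
) -> float | None:
    """Summary statistic of modification values over genes in the term.

    Returns ``None`` (the undefined-value marker) when the condition's genes
    do not intersect the term.
    """
    if condition.modifications is None:
        raise UnsupportedModeError(
            f"condition {condition.id!r} carries no modification values"
        )
    if stat not in SUMMARY_STATS:
        raise DomainError(f"unknown summary statistic {stat!r}")
    values = [
        condition.modifications[g] for g in condition.genes if g in set(term_genes)
    ]
    if not values:
        return None
    return float(SUMMARY_STATS[stat](values))


def enrich(
    condition: Condition,
    annotation: GeneAnnotation,
    alpha: float = 0.05,
    method: str = "fdr",
    stat: str = "median",
) -> EnrichmentResult:
    """Over-representation analysis of one condition against an annotation.

    Genes absent from the universe are dropped (count logged).  Every term
    with overlap >= 1 is tested; the correction spans exactly those terms.
    Records are filtered to adjusted p <= ``alpha`` and sorted by
    (adjusted p, term id).
    """
    if not 0 <= alpha <= 1:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    query = [g for g in condition.genes if g in annotation.universe]
    dropped = len(condition.genes) - len(query)
    if dropped:
        logger.info(
            "condition %s: %d gene(s) not in universe dropped", condition.id, dropped
        )
    if not query:
        warnings.warn(
            f"condition {condition.id!r}: no genes intersect the universe",
            stacklevel=2,
        )
        return EnrichmentResult(condition_id=condition.id)

    query_set = set(query)
    universe_size = len(annotation.universe)
    tested: list[tuple[str, int, int]] = []
    for term, genes in annotation.term_to_genes.items():
        overlap = len(query_set & genes)
        if overlap >= 1:
            tested.append((term, overlap, len(genes)))
    if not tested:
        return EnrichmentResult(condition_id=condition.id)

    raw = [
        hypergeometric_pvalue(o, k, len(query), universe_size) for _, o, k in tested
    ]
    adj = adjust_pvalues(raw, method=method)

    has_mods = condition.modifications is not None
    records = []
    for (term, overlap, _), rp, ap in zip(tested, raw, adj):
        if ap <= alpha:
            mv = (
                modification_summary(condition, annotation.term_to_genes[term], stat)
                if has_mods
                else None
            )
            records.append(
                EnrichmentRecord(
                    term=term, raw_p=rp, adj_p=ap, overlap=overlap, mv_summary=mv
                )
            )
    records.sort(key=lambda r: (r.adj_p, r.term))
    return EnrichmentResult(condition_id=condition.id, records=records)


def cell_value(record: EnrichmentRecord, mode: str = "enrichment_p") -> float:
    """Value a record contributes to the condition x term matrix.

    ``enrichment_p``: the adjusted p-value; ``modification``: the summarised
    modification value; ``combined``: ``MV * -log10(adjusted p)``.
    """
    if mode == "enrichment_p":
        return record.adj_p
    if mode not in VALUE_MODES:
        raise DomainError(f"unknown value mode {mode!r}")
    if record.mv_summary is None:
        raise UnsupportedModeError(
            f"mode {mode!r} requires a modification summary (term {record.term!r})"
        )
    if mode == "modification":
        return record.mv_summary
    return record.mv_summary * -np.log10(record.adj_p)


def write_enrichment_tsv(results: Sequence[EnrichmentResult], stream: TextIO) -> None:
    """Export enrichment records as TSV with a header row."""
    stream.write("condition\tterm\traw_p\tadj_p\toverlap\tmv_summary\n")
    for res in results:
        for r in res.records:
            mv = "" if r.mv_summary is None else f"{r.mv_summary:.10g}"
            stream.write(
                f"{res.condition_id}\t{r.term}\t{r.raw_p:.10g}\t{r.adj_p:.10g}"
                f"\t{r.overlap}\t{mv}\n"
            )


def read_enrichment_tsv(stream: TextIO) -> list[EnrichmentResult]:
    """Parse the TSV written by :func:`write_enrichment_tsv`."""
    results: dict[str, EnrichmentResult] = {}
    header = stream.readline()
    if not header.startswith("condition\t"):
        raise InputError("not an enrichment TSV (missing header)")
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            raise InputError(f"line {lineno}: expected 6 columns")
        cond, term, raw_p, adj_p, overlap, mv = parts
        rec = EnrichmentRecord(
            term=term,
            raw_p=float(raw_p),
            adj_p=float(adj_p),
            overlap=int(overlap),
            mv_summary=float(mv) if mv else None,
        )
        results.setdefault(cond, EnrichmentResult(condition_id=cond)).records.append(rec)
    return list(results.values())


def read_gene_annotation(
    stream: TextIO, universe: Iterable[str] | None = None
) -> GeneAnnotation:
    """Read a 2-column TSV ``term-id<TAB>gene-id`` into a GeneAnnotation."""
    pairs = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not all(p.strip() for p in parts):
            raise InputError(f"line {lineno}: expected term-id, gene-id columns")
        pairs.append((parts[0].strip(), parts[1].strip()))
    return GeneAnnotation.from_pairs(pairs, universe=universe)


def read_mapping(stream: TextIO) -> dict[str, str]:
    """Read a 2-column alias -> canonical gene-id mapping TSV."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise InputError(f"line {lineno}: expected alias, canonical columns")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def apply_mapping(condition: Condition, mapping: Mapping[str, str]) -> Condition:
    """Rename genes through an alias map, keeping modifications aligned.

    If two aliases collapse onto one canonical id, the first occurrence wins.
    """
    genes: list[str] = []
    mods: dict[str, float] | None = (
        {} if condition.modifications is not None else None
    )
    for g in condition.genes:
        canon = mapping.get(g, g)
        if canon in genes:
            continue
        genes.append(canon)
        if mods is not None:
            mods[canon] = condition.modifications[g]
    return Condition(id=condition.id, group=condition.group, genes=genes, modifications=mods)
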