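"""Condition x term matrices and their collapse to hierarchy levels.

The term matrix ``Ter`` holds one row per condition and one column per term
enriched in at least one condition; a cell is defined only where the term is
enriched in that condition (NaN marks undefined).  Level matrices collapse
term columns to level-1 or level-2 categories with a summary statistic taken
over the *defined* descendant-term cells — undefined cells never enter the
statistic, and higher levels are always computed from the term matrix
directly (a median of level-2 medians is not the level-1 median).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import SUMMARY_STATS, EnrichmentResult, cell_value
from .errors import DomainError, InputError, UnsupportedModeError
from .hierarchy import ThreeLevelHierarchy

__all__ = [
    "TermMatrix",
    "LevelMatrix",
    "build_term_matrix",
    "summarize_to_level",
    "apply_sign_mode",
    "filter_view",
    "term_sets",
]

UNMAPPED = "unmapped"

#: value modes that carry sign information (sign display allowed)
SIGNED_MODES = ("modification", "combined", "sign")


@dataclass
class TermMatrix:
    """Conditions x enriched-terms value matrix (NaN = not enriched)."""

    data: pd.DataFrame  # index: condition ids, columns: term ids
    mode: str

    @property
    def conditions(self) -> list[str]:
        return list(self.data.index)

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path, mode: str = "enrichment_p") -> "TermMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(data=df, mode=mode)


@dataclass
class LevelMatrix:
    """Conditions x categories matrix at hierarchy level 1 or 2."""

    data: pd.DataFrame  # index: condition ids, columns: category ids
    level: int
    parents: dict[str, str]  # category -> level-1 parent (self at level 1)
    mode: str

    @property
    def conditions(self) -> list[str]:
        return list(self.data.index)

    @property
    def categories(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="")


def build_term_matrix(
    results: Sequence[EnrichmentResult], mode: str = "enrichment_p"
) -> TermMatrix:
    """Assemble the Ter matrix from per-condition enrichment results.

    Columns are the union of enriched terms across conditions (sorted);
    cells are filled through :func:`~enrichgrid.enrichment.cell_value`.
    """
    ids = [r.condition_id for r in results]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate condition ids in enrichment results")
    all_terms = sorted(set().union(*(r.terms for r in results))) if results else []
    if not all_terms:
        warnings.warn("no enriched terms in any condition", stacklevel=2)
    values = np.full((len(ids), len(all_terms)), np.nan)
    col = {t: j for j, t in enumerate(all_terms)}
    for i, res in enumerate(results):
        for rec in res.records:
            values[i, col[rec.term]] = cell_value(rec, mode)
    df = pd.DataFrame(values, index=ids, columns=all_terms)
    return TermMatrix(data=df, mode=mode)


def _category_columns(
    terms: Iterable[str], h: ThreeLevelHierarchy, level: int
) -> tuple[list[str], dict[str, str], dict[str, set[str]]]:
    """Ordered categories, their level-1 parents, and category -> term map.

    Category order follows the hierarchy (level-1 in source order, level-2
    grouped under its parent); categories without any enriched descendant
    are omitted.  Terms missing from the hierarchy fall into ``unmapped``.
    """
    terms = list(terms)
    members: dict[str, set[str]] = {}
    parents: dict[str, str] = {}
    unmapped: set[str] = set()
    for t in terms:
        pairs = h.memberships.get(t)
        if not pairs:
            unmapped.add(t)
            continue
        for l1, l2 in pairs:
            cat = l1 if level == 1 else l2
            members.setdefault(cat, set()).add(t)
            parents.setdefault(cat, l1)

    if level == 1:
        ordered = [c for c in h.level1_categories() if c in members]
    else:
        ordered = [c for c in h.level2_categories() if c in members]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} enriched term(s) absent from hierarchy -> 'unmapped'",
            stacklevel=3,
        )
        members[UNMAPPED] = unmapped
        parents[UNMAPPED] = UNMAPPED
        ordered.append(UNMAPPED)
    return ordered, parents, members


def summarize_to_level(
    tm: TermMatrix, h: ThreeLevelHierarchy, level: int, stat: str = "median"
) -> LevelMatrix:
    """Collapse the term matrix to level-1 or level-2 categories.

    A category cell is the chosen statistic over the condition's defined
    cells of the category's descendant terms, and is defined iff at least
    one descendant is enriched.  A term carrying several memberships
    contributes to every category it belongs to (once per category).
    """
    if level not in (1, 2):
        raise DomainError(f"level must be 1 or 2, got {level}")
    if stat not in SUMMARY_STATS:
        raise DomainError(f"unknown summary statistic {stat!r}")
    fn = SUMMARY_STATS[stat]
    ordered, parents, members = _category_columns(tm.terms, h, level)
    values = np.full((len(tm.conditions), len(ordered)), np.nan)
    for j, cat in enumerate(ordered):
        sub = tm.data[sorted(members[cat])].to_numpy()
        for i in range(sub.shape[0]):
            defined = sub[i][~np.isnan(sub[i])]
            if defined.size:
                values[i, j] = fn(defined)
    df = pd.DataFrame(values, index=tm.conditions, columns=ordered)
    return LevelMatrix(
        data=df,
        level=level,
        parents={c: parents[c] for c in ordered},
        mode=tm.mode,
    )


def apply_sign_mode(m: TermMatrix | LevelMatrix) -> TermMatrix | LevelMatrix:
    """Reduce defined cells to their sign {-1, 0, +1}; NaNs stay undefined.

    Only meaningful for value modes that carry signed modification
    information; p-values have no sign.
    """
    if m.mode not in SIGNED_MODES:
        raise UnsupportedModeError(
            f"sign display needs a signed value mode, not {m.mode!r}"
        )
    signed = m.data.copy()
    mask = signed.notna()
    signed[mask] = np.sign(signed[mask])
    if isinstance(m, TermMatrix):
        return TermMatrix(data=signed, mode="sign")
    return LevelMatrix(data=signed, level=m.level, parents=dict(m.parents), mode="sign")


def filter_view(
    m: TermMatrix | LevelMatrix,
    h: ThreeLevelHierarchy,
    keep_categories: Mapping[int, Iterable[str]] | None = None,
    keep_conditions: Iterable[str] | None = None,
) -> TermMatrix | LevelMatrix:
    """Restrict a matrix to chosen categories and/or conditions.

    ``keep_categories`` maps a hierarchy level (1 or 2) to category ids; a
    column survives if it belongs to (or descends from) a kept category at
    every constrained level.  Ordering is preserved.
    """
    df = m.data
    if keep_conditions is not None:
        keep_c = list(keep_conditions)
        unknown = [c for c in keep_c if c not in df.index]
        if unknown:
            raise InputError(f"unknown condition id(s): {unknown}")
        df = df.loc[[c for c in df.index if c in set(keep_c)]]

    if keep_categories:
        for lvl, cats in keep_categories.items():
            if lvl not in (1, 2):
                raise DomainError(f"category filter level must be 1 or 2, got {lvl}")
            cats = set(cats)
            known = set(h.categories(lvl)) | {UNMAPPED}
            unknown = sorted(cats - known)
            if unknown:
                raise InputError(f"unknown level-{lvl} category id(s): {unknown}")
            keep_cols = []
            for colname in df.columns:
                if isinstance(m, LevelMatrix):
                    if m.level == lvl:
                        ok = colname in cats
                    elif m.level == 2 and lvl == 1:
                        ok = m.parents.get(colname) in cats
                    else:  # level-1 matrix filtered by level-2 categories
                        children = set(h.level2_by_parent().get(colname, []))
                        ok = bool(children & cats)
                else:
                    pairs = h.memberships.get(colname, set())
                    idx = 0 if lvl == 1 else 1
                    ok = (
                        any(p[idx] in cats for p in pairs)
                        or (not pairs and UNMAPPED in cats)
                    )
                if ok:
                    keep_cols.append(colname)
            df = df[keep_cols]

    if df.size == 0:
        warnings.warn("filter produced an empty view", stacklevel=2)
    if isinstance(m, TermMatrix):
        return TermMatrix(data=df.copy(), mode=m.mode)
    parents = {c: m.parents[c] for c in df.columns}
    return LevelMatrix(data=df.copy(), level=m.level, parents=parents, mode=m.mode)


def term_sets(m: TermMatrix | LevelMatrix) -> dict[str, set[str]]:
    """Per-condition sets of defined (enriched) columns, in row order."""
    out: dict[str, set[str]] = {}
    for cond in m.data.index:
        row = m.data.loc[cond]
        out[cond] = set(row.index[row.notna()])
    return out
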