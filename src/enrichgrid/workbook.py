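"""Reading and writing the multi-condition workbook contract.

The input is either an XLSX workbook with one sheet per experimental
condition (column 1: gene id; optional column 2: numeric modification
value; no header row) plus a sheet named ``groups`` (condition id, group
label) — or, equivalently, a directory of TSV files ``<condition-id>.tsv``
with a ``groups.tsv``.  Conditions are ordered as listed in the groups
sheet.
"""

from __future__ import annotations

from pathlib import Path

import openpyxl

from .enrichment import Condition, ConditionSet
from .errors import FormatError, InputError

__all__ = ["read_workbook", "write_workbook"]

GROUPS_SHEET = "groups"


def _build_condition(cond_id: str, group: str, rows, where: str) -> Condition:
    """Turn (gene, modification) rows into a Condition with line checks."""
    genes: list[str] = []
    mods: list[float | None] = []
    for lineno, row in rows:
        gene = row[0]
        if gene is None or str(gene).strip() == "":
            continue
        gene = str(gene).strip()
        mod = row[1] if len(row) > 1 else None
        if mod is not None and str(mod).strip() != "":
            try:
                mods.append(float(mod))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{where}: non-numeric modification value {mod!r}", line=lineno
                ) from None
        else:
            mods.append(None)
        genes.append(gene)
    if not genes:
        raise InputError(f"{where}: condition sheet has no genes")
    have = [m is not None for m in mods]
    if any(have) and not all(have):
        first_missing = have.index(False) + 1
        raise FormatError(
            f"{where}: modification values must cover every gene or none "
            f"(first missing at record {first_missing})"
        )
    modifications = dict(zip(genes, mods)) if all(have) else None
    return Condition(id=cond_id, group=group, genes=genes, modifications=modifications)


def _read_tsv_dir(path: Path) -> ConditionSet:
    groups_file = path / f"{GROUPS_SHEET}.tsv"
    if not groups_file.exists():
        raise InputError(f"missing groups sheet: {groups_file}")
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(groups_file.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{groups_file}: expected condition-id, group columns", line=lineno
            )
        order.append((parts[0].strip(), parts[1].strip()))
    conditions = []
    for cond_id, group in order:
        sheet = path / f"{cond_id}.tsv"
        if not sheet.exists():
            raise InputError(
                f"groups sheet references condition {cond_id!r} but {sheet} is missing"
            )
        rows = [
            (lineno, line.rstrip("\n").split("\t"))
            for lineno, line in enumerate(
                sheet.read_text().splitlines(), start=1
            )
            if line.strip()
        ]
        conditions.append(_build_condition(cond_id, group, rows, where=str(sheet)))
    return ConditionSet(conditions)


def _read_xlsx(path: Path) -> ConditionSet:
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        sheet_names = {s.lower(): s for s in wb.sheetnames}
        if GROUPS_SHEET not in sheet_names:
            raise InputError(f"missing {GROUPS_SHEET!r} sheet in {path}")
        groups_ws = wb[sheet_names[GROUPS_SHEET]]
        order: list[tuple[str, str]] = []
        for lineno, row in enumerate(groups_ws.iter_rows(values_only=True), start=1):
            if row is None or row[0] is None:
                continue
            if len(row) < 2 or row[1] is None:
                raise FormatError(
                    f"{path}[{GROUPS_SHEET}]: expected condition-id, group columns",
                    line=lineno,
                )
            order.append((str(row[0]).strip(), str(row[1]).strip()))
        conditions = []
        for cond_id, group in order:
            if cond_id not in wb.sheetnames:
                raise InputError(
                    f"groups sheet references condition {cond_id!r} "
                    f"but workbook has no such sheet"
                )
            ws = wb[cond_id]
            rows = [
                (lineno, list(row))
                for lineno, row in enumerate(ws.iter_rows(values_only=True), start=1)
                if row is not None and row[0] is not None
            ]
            conditions.append(
                _build_condition(cond_id, group, rows, where=f"{path}[{cond_id}]")
            )
        return ConditionSet(conditions)
    finally:
        wb.close()


def read_workbook(path: str | Path) -> ConditionSet:
    """Read a condition workbook (XLSX file or TSV directory)."""
    path = Path(path)
    if path.is_dir():
        return _read_tsv_dir(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return _read_xlsx(path)
    raise InputError(f"workbook must be an .xlsx file or a TSV directory: {path}")


def write_workbook(cs: ConditionSet, path: str | Path) -> Path:
    """Write a ConditionSet in the input dialect implied by ``path``.

    A path ending in ``.xlsx`` produces a workbook; anything else is
    treated as a directory of TSVs.
    """
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for cond in cs:
            ws = wb.create_sheet(title=cond.id)
            for gene in cond.genes:
                if cond.modifications is not None:
                    ws.append([gene, cond.modifications[gene]])
                else:
                    ws.append([gene])
        ws = wb.create_sheet(title=GROUPS_SHEET)
        for cond in cs:
            ws.append([cond.id, cond.group])
        path.parent.mkdir(parents=True, exist_ok=True)
        wb.save(path)
        return path
    path.mkdir(parents=True, exist_ok=True)
    with open(path / f"{GROUPS_SHEET}.tsv", "w") as fh:
        for cond in cs:
            fh.write(f"{cond.id}\t{cond.group}\n")
    for cond in cs:
        with open(path / f"{cond.id}.tsv", "w") as fh:
            for gene in cond.genes:
                if cond.modifications is not None:
                    fh.write(f"{gene}\t{cond.modifications[gene]:.10g}\n")
                else:
                    fh.write(f"{gene}\n")
    return path
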