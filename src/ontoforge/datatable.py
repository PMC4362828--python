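"""The populated quick-term template: a rectangular grid of cell strings.

One row per to-be-generated (or to-be-edited) ontology term.  Columns are
addressed spreadsheet-style by letters (A, B, ..., Z, AA, ...), matching the
``{$columnA}`` variable convention used in axiom patterns.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Union

from .errors import TableFormatError

Source = Union[str, Path, BinaryIO]


@dataclass
class DataTable:
    """A rectangular grid of cell strings with an optional header row.

    All rows are padded with empty strings to ``width``, so every cell access
    inside the grid is well defined; columns beyond ``width`` read as ``""``.
    """

    header: list[str] | None = None
    rows: list[list[str]] = field(default_factory=list)
    width: int = 0

    def __post_init__(self):
        w = self.width
        for r in self.rows:
            w = max(w, len(r))
        if self.header is not None:
            w = max(w, len(self.header))
        self.width = w
        for r in self.rows:
            r.extend([""] * (self.width - len(r)))
        if self.header is not None:
            self.header.extend([""] * (self.width - len(self.header)))


def column_index(letters: str) -> int:
    """Map spreadsheet column letters to a zero-based index.

    Bijective base-26: A->0 ... Z->25, AA->26, AB->27, ...  Case-insensitive.
    """
    if not letters or not letters.isalpha() or not letters.isascii():
        raise TableFormatError(f"invalid column letters: {letters!r}")
    n = 0
    for ch in letters.upper():
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n - 1


def cell(table: DataTable, row: int, letters: str) -> str:
    """Return the cell at data row ``row`` (zero-based) and column ``letters``.

    Columns beyond the table width return the empty string; the header row is
    never addressable through this function.
    """
    if not 0 <= row < len(table.rows):
        raise IndexError(f"row {row} out of range (0..{len(table.rows) - 1})")
    idx = column_index(letters)
    r = table.rows[row]
    return r[idx] if idx < len(r) else ""


def _render_xlsx_value(value) -> str:
    # Mirror the display text a spreadsheet shows, not Python's repr.
    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            return data.decode("utf-8-sig")
        return data.lstrip("﻿")
    try:
        return Path(source).read_text(encoding="utf-8-sig")
    except OSError as exc:
        raise TableFormatError(f"cannot read table: {exc}") from exc


def read_table(source: Source, format: str = "tsv", has_header: bool = True) -> DataTable:
    """Read a populated template in TSV, CSV, or XLSX format.

    TSV is tab-delimited with no quoting; CSV uses RFC-4180 quoting; XLSX reads
    the first worksheet only (a warning is issued if the workbook has more).
    Cell whitespace is preserved; trailing fully-empty rows are dropped; a UTF-8
    byte-order mark is tolerated and stripped.
    """
    fmt = format.lower()
    if fmt == "tsv":
        text = _read_text(source)
        if text.endswith("\n"):
            text = text[:-1]
        raw = [] if text == "" else [
            line.rstrip("\r").split("\t") for line in text.split("\n")
        ]
    elif fmt == "csv":
        text = _read_text(source)
        try:
            raw = [list(r) for r in csv.reader(io.StringIO(text))]
        except csv.Error as exc:
            raise TableFormatError(f"malformed CSV: {exc}") from exc
    elif fmt == "xlsx":
        from openpyxl import load_workbook

        if hasattr(source, "read"):
            data = source.read()
            handle = io.BytesIO(data if isinstance(data, bytes) else data.encode())
        else:
            if not Path(source).exists():
                raise TableFormatError(f"cannot read table: {source}")
            handle = source
        try:
            wb = load_workbook(handle, read_only=True, data_only=True)
        except Exception as exc:  # openpyxl raises a zoo of types here
            raise TableFormatError(f"malformed XLSX: {exc}") from exc
        if len(wb.sheetnames) > 1:
            warnings.warn(
                f"workbook has {len(wb.sheetnames)} sheets; only the first "
                f"({wb.sheetnames[0]!r}) is read",
                stacklevel=2,
            )
        ws = wb[wb.sheetnames[0]]
        raw = [[_render_xlsx_value(c) for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
    else:
        raise TableFormatError(f"unknown table format: {format!r}")

    while raw and all(c == "" for c in raw[-1]):
        raw.pop()

    header = None
    if has_header and raw:
        header = raw.pop(0)
    return DataTable(header=header, rows=raw)


def to_tsv(table: DataTable) -> str:
    """Serialize a table back to tab-delimited text (header first, if any)."""
    out = []
    if table.header is not None:
        out.append("\t".join(table.header))
    out.extend("\t".join(r) for r in table.rows)
    return "\n".join(out) + ("\n" if out else "")
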