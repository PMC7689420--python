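"""Tabular input: delimited text, Excel workbooks, and remote CSV by URL.

A volcano plot needs three things from a screen export: one numeric
effect-size column (typically log2 fold change), one numeric significance
column (typically -log10 p-value) and, optionally, a column of gene or
protein names.  This module reads the accepted dialects into a
:class:`RawTable` of text cells and then maps user-chosen columns onto
:class:`VolcanoData`, coercing to numbers and dropping (while counting)
rows that do not yield finite coordinates.
"""

from __future__ import annotations

import csv
import io as _stdio
import math
import urllib.request
import urllib.error
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import (
    ColumnNotFoundError,
    FileTooLargeError,
    NoNumericDataError,
    RemoteFetchError,
    SheetNotFoundError,
    UndelimitedInputError,
    UnsupportedFormatError,
    UnsupportedSchemeError,
)

#: Delimiters tried by :func:`sniff_delimiter`, in tie-breaking order.
DEFAULT_DELIMITERS: tuple[str, ...] = (",", "\t", ";")

#: Default size guard in bytes (the standalone-app limit of ~10 Mb).
DEFAULT_MAX_BYTES: int = 10 * 1024 * 1024

_TEXT_EXTENSIONS = {"csv", "txt"}
_SHEET_EXTENSIONS = {"xls", "xlsx"}


@dataclass(frozen=True)
class VolcanoRecord:
    """One gene/protein point: identifier, effect size and significance.

    ``x`` is the effect coordinate (log2 fold change; 0 means no change)
    and ``y`` the significance coordinate (-log10 p, larger is more
    significant).  ``category`` is assigned by threshold classification and
    is one of ``"unchanged"``, ``"decreased"``, ``"increased"`` or ``None``.
    """

    name: str
    x: float
    y: float
    category: Optional[str] = None

    def with_category(self, category: str) -> "VolcanoRecord":
        return VolcanoRecord(self.name, self.x, self.y, category)


@dataclass
class RawTable:
    """A parsed table of text cells, prior to any column mapping."""

    column_names: list[str]
    rows: list[tuple[str, ...]]
    source_descriptor: str = ""

    def __post_init__(self) -> None:
        self.column_names = _dedupe_columns(self.column_names)
        width = len(self.column_names)
        fixed: list[tuple[str, ...]] = []
        for i, row in enumerate(self.rows):
            row = tuple(row)
            if len(row) > width:
                raise UnsupportedFormatError(
                    f"row {i + 1} has {len(row)} cells but the header "
                    f"declares {width} columns"
                )
            if len(row) < width:
                row = row + ("",) * (width - len(row))
            fixed.append(row)
        self.rows = fixed


@dataclass
class VolcanoData:
    """Coordinate-mapped records plus provenance of the mapping."""

    records: list[VolcanoRecord]
    x_label: str
    y_label: str
    name_label: str = "row-index"
    n_dropped: int = 0
    source_descriptor: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame with name/x/y/category columns."""
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "category": [r.category for r in self.records],
            }
        )


def _dedupe_columns(names: Sequence[str]) -> list[str]:
    # whitespace-normalise, then suffix duplicates _2, _3, ... in order seen
    seen: dict[str, int] = {}
    out: list[str] = []
    for raw in names:
        name = " ".join(str(raw).split())
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 1
            out.append(name)
    return out


def sniff_delimiter(
    sample: str, candidates: Sequence[str] = DEFAULT_DELIMITERS
) -> str:
    """Pick the delimiter giving the most consistent field count.

    The first 10 lines are split with each candidate; a candidate scores
    the number of lines whose field count equals the first line's count,
    provided that count is at least 2.  Ties break in candidate order
    (default comma > tab > semicolon), making the choice deterministic.

    Raises
    ------
    UndelimitedInputError
        If no candidate splits the first line into two or more fields.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    lines = [ln for ln in sample.splitlines() if ln.strip()][:10]
    if not lines:
        raise UndelimitedInputError("input contains no non-empty lines")
    best: Optional[str] = None
    best_score = -1
    for cand in candidates:
        first = len(lines[0].split(cand))
        if first < 2:
            continue
        score = sum(1 for ln in lines if len(ln.split(cand)) == first)
        if score > best_score:
            best, best_score = cand, score
    if best is None:
        raise UndelimitedInputError(
            "undelimited input: no candidate delimiter yields at least "
            "two fields on the first line"
        )
    return best


def read_table(
    data: bytes,
    filename_hint: str,
    sheet: Optional[str] = None,
    max_bytes: int = DEFAULT_MAX_BYTES,
) -> RawTable:
    """Parse CSV/TXT bytes (delimiter auto-sniffed) or an Excel workbook.

    The first row is always taken as the header.  ``sheet`` selects a
    workbook sheet by name; when absent the first sheet is used.  A size
    guard (default 10 Mb) rejects oversized inputs up front.
    """
    if max_bytes is not None and len(data) > max_bytes:
        raise FileTooLargeError(
            f"file too large: {len(data)} bytes exceeds the "
            f"{max_bytes} byte limit"
        )
    ext = filename_hint.rsplit(".", 1)[-1].lower() if "." in filename_hint else ""
    if ext in _TEXT_EXTENSIONS:
        return _read_delimited(data, filename_hint)
    if ext in _SHEET_EXTENSIONS:
        return _read_workbook(data, filename_hint, ext, sheet)
    raise UnsupportedFormatError(
        f"unsupported format {filename_hint!r}: expected a .csv, .txt, "
        ".xls or .xlsx file"
    )


def _read_delimited(data: bytes, descriptor: str) -> RawTable:
    text = data.decode("utf-8-sig", errors="replace")
    delim = sniff_delimiter(text)
    reader = csv.reader(_stdio.StringIO(text), delimiter=delim)
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    if not rows:
        raise UndelimitedInputError("input contains no data")
    header, body = rows[0], rows[1:]
    width = len(header)
    padded = [tuple(r) + ("",) * (width - len(r)) if len(r) < width else tuple(r)
              for r in body]
    return RawTable(list(header), padded, source_descriptor=descriptor)


def _read_workbook(
    data: bytes, descriptor: str, ext: str, sheet: Optional[str]
) -> RawTable:
    if ext == "xls":
        # pandas needs the legacy xlrd engine for .xls, which this package
        # does not depend on; .xlsx covers modern exports.
        raise UnsupportedFormatError(
            "unsupported format: legacy .xls workbooks are not readable "
            "here; re-save as .xlsx or .csv"
        )
    book = pd.ExcelFile(_stdio.BytesIO(data), engine="openpyxl")
    if sheet is None:
        sheet_name = book.sheet_names[0]
    elif sheet in book.sheet_names:
        sheet_name = sheet
    else:
        raise SheetNotFoundError(
            f"sheet not found: {sheet!r}; available sheets: "
            + ", ".join(repr(s) for s in book.sheet_names)
        )
    frame = book.parse(sheet_name, header=0, dtype=str)
    frame = frame.fillna("")
    return RawTable(
        [str(c) for c in frame.columns],
        [tuple(str(v) for v in row) for row in frame.itertuples(index=False)],
        source_descriptor=f"{descriptor}#{sheet_name}",
    )


def fetch_remote(url: str, timeout: float = 30.0) -> tuple[bytes, str]:
    """Download a table from an online repository; one attempt, no retry.

    Returns the response body and a filename hint taken from the final
    path segment of the URL.
    """
    scheme = url.split(":", 1)[0].lower() if ":" in url else ""
    if scheme not in ("http", "https"):
        raise UnsupportedSchemeError(
            f"unsupported scheme {scheme!r}: only http/https URLs are accepted"
        )
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            status = getattr(resp, "status", 200)
            if not 200 <= status < 300:
                raise RemoteFetchError(f"remote fetch failed: HTTP {status}")
            body = resp.read()
    except urllib.error.HTTPError as exc:
        raise RemoteFetchError(f"remote fetch failed: HTTP {exc.code}") from exc
    except (urllib.error.URLError, OSError) as exc:
        raise RemoteFetchError(f"remote fetch failed: {exc}") from exc
    path = url.split("?", 1)[0].rstrip("/")
    hint = path.rsplit("/", 1)[-1] or "remote.csv"
    return body, hint


def _coerce(cell: str) -> float:
    try:
        return float(str(cell).strip())
    except (TypeError, ValueError):
        return math.nan


def select_columns(
    table: RawTable,
    x_col: str,
    y_col: str,
    name_col: Optional[str] = None,
    cap_infinite: Optional[float] = None,
) -> VolcanoData:
    """Map chosen columns onto volcano coordinates.

    Cells of ``x_col``/``y_col`` are coerced to floats; rows with
    non-coercible or non-finite coordinates are dropped and counted in
    ``n_dropped``.  Names come from ``name_col`` when given, else are
    generated as ``row_<i>`` (1-based source position).

    ``cap_infinite`` opts into clamping infinite significance values
    (p = 0 gives y = inf) to the given finite value instead of dropping
    the row; by default such rows are dropped, which is the conservative,
    reportable choice.
    """
    if x_col == y_col:
        raise ColumnNotFoundError(
            "x and y must name distinct columns; both are "
            f"{x_col!r}"
        )
    cols = table.column_names
    for needed in filter(None, (x_col, y_col, name_col)):
        if needed not in cols:
            raise ColumnNotFoundError(
                f"column not found: {needed!r}; available columns: "
                + ", ".join(repr(c) for c in cols)
            )
    xi, yi = cols.index(x_col), cols.index(y_col)
    ni = cols.index(name_col) if name_col else None

    records: list[VolcanoRecord] = []
    dropped = 0
    for i, row in enumerate(table.rows):
        x, y = _coerce(row[xi]), _coerce(row[yi])
        if cap_infinite is not None:
            if math.isinf(x):
                x = math.copysign(cap_infinite, x)
            if math.isinf(y):
                y = math.copysign(cap_infinite, y)
        if not (math.isfinite(x) and math.isfinite(y)):
            dropped += 1
            continue
        if ni is not None and str(row[ni]).strip():
            name = str(row[ni]).strip()
        else:
            name = f"row_{i + 1}"
        records.append(VolcanoRecord(name, x, y))
    if not records:
        raise NoNumericDataError(
            f"no numeric data: none of the {len(table.rows)} rows has "
            f"finite values in columns {x_col!r} and {y_col!r}"
        )
    return VolcanoData(
        records,
        x_label=x_col,
        y_label=y_col,
        name_label=name_col or "row-index",
        n_dropped=dropped,
        source_descriptor=table.source_descriptor,
    )


def read_volcano(
    data: bytes,
    filename_hint: str,
    x_col: str,
    y_col: str,
    name_col: Optional[str] = None,
    sheet: Optional[str] = None,
    max_bytes: int = DEFAULT_MAX_BYTES,
    cap_infinite: Optional[float] = None,
) -> VolcanoData:
    """Convenience: :func:`read_table` followed by :func:`select_columns`."""
    table = read_table(data, filename_hint, sheet=sheet, max_bytes=max_bytes)
    return select_columns(table, x_col, y_col, name_col, cap_infinite=cap_infinite)
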