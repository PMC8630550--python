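"""Readers and writers for every file dialect the tool touches.

Three formats are supported:

* the plate-reader workbook (XLSX): two 8 x 12 luminescence tables — firefly
  first, renilla second in reading order — each flanked by row labels A-H and
  column headers 1-12, in the dialect of the Promega GloMax export;
* the design table (CSV): one row per well mapping it to experimental
  conditions;
* the tidy table (CSV): one observation per row with well, condition
  column(s), firefly signal and optionally the renilla control, plus computed
  ``ratio``/``fold_change`` columns on output.

Workbook block positions are auto-detected by scanning for labelled 8 x 12
numeric regions, so metadata rows (protocol names, timestamps) above or
between the tables are tolerated; an explicit :class:`WorkbookLayout` can
override detection.  All writers are deterministic: identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import datetime
import io
import logging
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import openpyxl
import pandas as pd

from .core_model import (
    DesignTable,
    PlateReadings,
    ROW_LETTERS,
    N_COLUMNS,
    TidyExperiment,
    ValidationError,
    parse_well,
)

logger = logging.getLogger(__name__)

#: Header names recognized (case-insensitively) for each tidy-column role.
WELL_NAMES = {"well", "wells"}
FIREFLY_NAMES = {"firefly", "signal", "intensity", "measurement"}
RENILLA_NAMES = {"renilla", "control", "reference"}
COMPUTED_NAMES = {"ratio": "ratio", "fold_change": "fold_change",
                  "fold change": "fold_change", "foldchange": "fold_change"}


class FormatError(ValidationError):
    """The file does not match the expected dialect."""


@dataclass(frozen=True)
class WorkbookLayout:
    """Explicit positions of the two data blocks in a plate workbook.

    Anchors are 1-based ``(row, column)`` coordinates of the top-left *data*
    cell (the A01 reading) of each 8 x 12 block.
    """

    sheet: str | int | None = None
    firefly_anchor: tuple[int, int] = (3, 2)
    renilla_anchor: tuple[int, int] = (14, 2)

    def __post_init__(self) -> None:
        fr, fc = self.firefly_anchor
        rr, rc = self.renilla_anchor
        # blocks span 8 rows x 12 columns; they must not overlap
        if abs(fr - rr) < len(ROW_LETTERS) and abs(fc - rc) < N_COLUMNS:
            raise ValidationError(
                "firefly and renilla blocks overlap: anchors "
                f"{self.firefly_anchor} and {self.renilla_anchor}"
            )


#: Layout used by :func:`write_glomax`; mirrors the instrument's sheet shape.
DEFAULT_LAYOUT = WorkbookLayout(sheet=0)


def _select_sheet(wb, sheet):
    if sheet is None:
        return wb[wb.sheetnames[0]]
    if isinstance(sheet, int):
        return wb[wb.sheetnames[sheet]]
    if sheet not in wb.sheetnames:
        raise FormatError(f"sheet {sheet!r} not in workbook {wb.sheetnames}")
    return wb[sheet]


def _cell_int(value) -> int | None:
    if isinstance(value, bool) or value is None:
        return None
    if isinstance(value, (int, float)) and float(value).is_integer():
        return int(value)
    if isinstance(value, str) and value.strip().isdigit():
        return int(value.strip())
    return None


def _cell_letter(value) -> str | None:
    if isinstance(value, str) and value.strip().upper() in ROW_LETTERS:
        return value.strip().upper()
    return None


def _find_blocks(grid: list[list]) -> list[tuple[int, int]]:
    """Locate candidate 8 x 12 blocks: header 1..12 above, labels A..H left.

    Returns 0-based ``(row, col)`` of each block's top-left data cell, in
    top-to-bottom, left-to-right reading order.
    """
    hits = []
    for r, row in enumerate(grid[:-len(ROW_LETTERS)]):
        for c in range(1, len(row) - N_COLUMNS + 1):
            if any(_cell_int(row[c + k]) != k + 1 for k in range(N_COLUMNS)):
                continue
            labels = [
                _cell_letter(grid[r + 1 + i][c - 1])
                if c - 1 < len(grid[r + 1 + i]) else None
                for i in range(len(ROW_LETTERS))
            ]
            if labels == list(ROW_LETTERS):
                hits.append((r + 1, c))
    return hits


def _read_block(grid, anchor0, channel):
    """Extract an 8x12 block; returns {well: value-or-None}."""
    r0, c0 = anchor0
    values = {}
    for i, letter in enumerate(ROW_LETTERS):
        for j in range(N_COLUMNS):
            try:
                v = grid[r0 + i][c0 + j]
            except IndexError:
                v = None
            well = f"{letter}{j + 1:02d}"
            if v is None or (isinstance(v, str) and not v.strip()):
                values[well] = None
            else:
                try:
                    values[well] = float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric {channel} reading {v!r} at well {well}"
                    )
    return values


def read_glomax(
    path,
    layout: WorkbookLayout | None = None,
    skip_blank: bool = True,
    allow_negative: bool = False,
    plate_id: str | None = None,
) -> PlateReadings:
    """Read a plate-reader workbook into paired firefly/renilla records.

    Without an explicit ``layout`` the two 8 x 12 blocks are auto-located by
    scanning for numeric regions flanked by A-H row labels and 1-12 column
    headers; the first block in reading order is firefly.  Wells blank in
    *both* channels are skipped (with a log entry) when ``skip_blank`` is
    set; a well blank in only one channel is always an error, because a
    missing control invalidates the pair.
    """
    path = Path(path)
    wb = openpyxl.load_workbook(path, data_only=True, read_only=False)
    sheet = layout.sheet if layout is not None else None
    ws = _select_sheet(wb, sheet)
    grid = [list(r) for r in ws.iter_rows(values_only=True)]
    if layout is not None:
        anchors = [
            (layout.firefly_anchor[0] - 1, layout.firefly_anchor[1] - 1),
            (layout.renilla_anchor[0] - 1, layout.renilla_anchor[1] - 1),
        ]
    else:
        found = _find_blocks(grid)
        if len(found) != 2:
            raise FormatError(
                f"expected 2 labelled 8x12 blocks on sheet {ws.title!r}, "
                f"found {len(found)} at {found}; supply a WorkbookLayout "
                "to override auto-detection"
            )
        anchors = found
    firefly = _read_block(grid, anchors[0], "firefly")
    renilla = _read_block(grid, anchors[1], "renilla")

    half_blank = sorted(
        w for w in firefly
        if (firefly[w] is None) != (renilla[w] is None)
    )
    if half_blank:
        raise FormatError(
            "wells with a reading in one channel but blank in the other: "
            f"{half_blank}"
        )
    blank = sorted(w for w in firefly if firefly[w] is None)
    if blank and not skip_blank:
        raise FormatError(f"blank wells present: {blank}")
    if blank:
        logger.info("skipping %d blank wells: %s", len(blank), blank)
    records = pd.DataFrame(
        {
            "well": [w for w in firefly if firefly[w] is not None],
        }
    )
    records["firefly"] = [firefly[w] for w in records["well"]]
    records["renilla"] = [renilla[w] for w in records["well"]]
    return PlateReadings(
        data=records,
        plate_id=plate_id or path.stem,
        allow_negative=allow_negative,
    )


_FIXED_STAMP = datetime.datetime(2000, 1, 1)


def _save_workbook_deterministic(wb, path) -> None:
    """Save an openpyxl workbook with fixed timestamps inside the zip."""
    wb.properties.created = _FIXED_STAMP
    wb.properties.modified = _FIXED_STAMP
    buf = io.BytesIO()
    wb.save(buf)
    buf.seek(0)
    with zipfile.ZipFile(buf) as src, zipfile.ZipFile(
        path, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in sorted(src.namelist()):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, src.read(name))


def write_glomax(
    readings: PlateReadings, path, layout: WorkbookLayout | None = None
) -> None:
    """Write a plate workbook that :func:`read_glomax` parses back losslessly.

    Wells absent from ``readings`` are left blank in both blocks.  Output is
    byte-stable: two writes of the same readings are identical files.
    """
    layout = layout or DEFAULT_LAYOUT
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Results"
    per_well = readings.data.set_index("well")
    for channel, (ar, ac) in (
        ("firefly", layout.firefly_anchor),
        ("renilla", layout.renilla_anchor),
    ):
        ws.cell(row=ar - 2, column=ac - 1, value=f"{channel} luminescence")
        for j in range(N_COLUMNS):
            ws.cell(row=ar - 1, column=ac + j, value=j + 1)
        for i, letter in enumerate(ROW_LETTERS):
            ws.cell(row=ar + i, column=ac - 1, value=letter)
            for j in range(N_COLUMNS):
                well = f"{letter}{j + 1:02d}"
                if well in per_well.index:
                    ws.cell(
                        row=ar + i,
                        column=ac + j,
                        value=float(per_well.loc[well, channel]),
                    )
    _save_workbook_deterministic(wb, path)


# ---------------------------------------------------------------------------
# CSV dialect helpers

def _sniff_sep(path) -> str:
    """Comma by default; the European ';' dialect is detected from the header."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    if header.count(";") > header.count(","):
        return ";"
    return ","


def read_design(path) -> DesignTable:
    """Read a design CSV: a ``well`` column plus >= 1 factor columns.

    The well header is matched case-insensitively; remaining columns become
    factors in file order.  Duplicate wells and factor-free files are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str,
                     encoding="utf-8-sig")
    df.columns = [str(c).strip() for c in df.columns]
    well_cols = [c for c in df.columns if c.lower() in WELL_NAMES]
    if not well_cols:
        raise FormatError(
            f"no well column in {path.name}; headers: {list(df.columns)}"
        )
    well_col = well_cols[0]
    factor_names = [c for c in df.columns if c != well_col]
    if not factor_names:
        raise FormatError(f"design {path.name} has no factor columns")
    df = df.rename(columns={well_col: "well"}).dropna(how="all")
    return DesignTable(data=df, factor_names=factor_names)


def merge_design(
    readings: PlateReadings,
    design: DesignTable,
    policy: str = "drop",
    separator: str = "_",
) -> TidyExperiment:
    """Inner-join plate readings with the design on well identity.

    Wells present in the readings but absent from the design are dropped
    with a logged count (``policy="strict"`` turns this into an error).
    Wells in the design but missing from the plate always error — a designed
    condition without a measurement signals a wrong file pairing.
    """
    if policy not in {"drop", "strict"}:
        raise ValidationError(f"unknown merge policy {policy!r}")
    rw = set(readings.data["well"])
    dw = set(design.data["well"])
    missing = sorted(dw - rw)
    if missing:
        raise ValidationError(
            f"design wells missing from plate readings: {missing}"
        )
    undesigned = sorted(rw - dw)
    if undesigned and policy == "strict":
        raise ValidationError(
            f"plate wells absent from the design: {undesigned}"
        )
    if undesigned:
        logger.info(
            "dropping %d wells without a design entry: %s",
            len(undesigned), undesigned,
        )
    merged = readings.data.merge(design.data, on="well", how="inner")
    merged = merged[["well", *design.factor_names, "firefly", "renilla"]]
    return TidyExperiment(
        data=merged,
        factor_names=list(design.factor_names),
        separator=separator,
        allow_negative=readings.allow_negative,
    )


def read_tidy(
    path,
    well_col: str | None = None,
    firefly_col: str | None = None,
    renilla_col: str | None = None,
    factor_cols: list[str] | None = None,
    separator: str = "_",
    allow_negative: bool = False,
) -> TidyExperiment:
    """Read a single tidy CSV with well, condition column(s) and signals.

    Column roles resolve in order: explicit arguments, then case-insensitive
    header match (``firefly``; ``renilla``/``control``/``reference`` for the
    internal control; ``ratio``/``fold_change`` for previously computed
    values), then positional fallback — the first unclaimed numeric column is
    the firefly signal.  Everything left over is a condition column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), encoding="utf-8-sig")
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    claimed: set[str] = set()

    def resolve(explicit, names):
        if explicit is not None:
            if explicit not in df.columns:
                raise FormatError(f"column {explicit!r} not in {path.name}")
            claimed.add(explicit)
            return explicit
        for n in names:
            if n in lower and lower[n] not in claimed:
                claimed.add(lower[n])
                return lower[n]
        return None

    well = resolve(well_col, WELL_NAMES)
    if well is None:
        raise FormatError(f"no well column in {path.name}")
    firefly = resolve(firefly_col, FIREFLY_NAMES)
    renilla = resolve(renilla_col, RENILLA_NAMES)
    computed = {}
    for name, target in COMPUTED_NAMES.items():
        if name in lower and lower[name] not in claimed:
            computed[target] = lower[name]
            claimed.add(lower[name])

    numeric_cols = [
        c for c in df.columns
        if c not in claimed and pd.to_numeric(df[c], errors="coerce").notna().all()
        and len(df) > 0
    ]
    if firefly is None:
        if not numeric_cols:
            raise FormatError(
                f"no numeric signal column found in {path.name}"
            )
        firefly = numeric_cols[0]
        claimed.add(firefly)

    if factor_cols is not None:
        unknown = [c for c in factor_cols if c not in df.columns]
        if unknown:
            raise FormatError(f"factor columns {unknown} not in {path.name}")
        factors = list(factor_cols)
    else:
        factors = [c for c in df.columns if c not in claimed]
    if not factors:
        raise FormatError(f"no condition columns left in {path.name}")

    for role, col in [("firefly", firefly), ("renilla", renilla)]:
        if col is None:
            continue
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                       & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"non-numeric entries in signal column {col!r} of "
                f"{path.name} at data rows {[int(i) + 2 for i in bad[:5]]}"
            )

    out = pd.DataFrame({"well": df[well]})
    for name in factors:
        out[name] = df[name]
    out["firefly"] = pd.to_numeric(df[firefly])
    if renilla is not None:
        out["renilla"] = pd.to_numeric(df[renilla])
    for target, col in computed.items():
        out[target] = pd.to_numeric(df[col])
    return TidyExperiment(
        data=out,
        factor_names=factors,
        separator=separator,
        allow_negative=allow_negative,
    )


def write_tidy(exp: TidyExperiment, path) -> None:
    """Write the experiment as a tidy CSV (one observation per row).

    Columns: well, one per factor, firefly, renilla (if present), ratio and
    fold_change (if computed).  Full float precision is kept so a re-read
    reproduces the table to well below 1e-9.
    """
    exp.data.to_csv(path, index=False, float_format="%.17g",
                    lineterminator="\n")
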