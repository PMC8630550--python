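"""Validated domain types shared by every stage of the dual-luciferase pipeline.

A dual-luciferase reporter experiment measures two luminescence channels per
well of a 96-well plate: *firefly* luciferase, driven by the regulatory
sequence under study, and *renilla* luciferase, a co-transfected internal
control on a constitutive promoter.  Dividing firefly by renilla per well
cancels well-to-well variation in cell density and transfection efficiency;
dividing that ratio by the mean ratio of a chosen reference condition (for
instance an empty-vector control) yields a fold change.

This module defines the in-memory containers for plate readings, experimental
designs, the merged tidy table, and summary statistics, plus the two primitive
operations everything else builds on: well-name parsing and condition-key
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGH"
N_COLUMNS = 12
PLATE_SIZE = len(ROW_LETTERS) * N_COLUMNS  # 96
DEFAULT_SEPARATOR = "_"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant of the pipeline."""


class SeparatorCollisionWarning(UserWarning):
    """A factor label contains the condition-key separator; keys may collide."""


@dataclass(frozen=True, order=True)
class WellId:
    """A well of a 96-well microplate: row letter A-H, column number 1-12.

    The canonical text form is the row letter followed by the zero-padded
    column, e.g. ``"A01"`` .. ``"H12"`` (always three characters).
    """

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise ValidationError(
                f"well row {self.row!r} outside A-{ROW_LETTERS[-1]}"
            )
        if not (1 <= self.column <= N_COLUMNS):
            raise ValidationError(
                f"well column {self.column!r} outside 1-{N_COLUMNS}"
            )

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"

    @property
    def text(self) -> str:
        """Canonical three-character name, e.g. ``"B07"``."""
        return str(self)

    @property
    def index(self) -> int:
        """Row-major position on the plate, 0 for A01 .. 95 for H12."""
        return ROW_LETTERS.index(self.row) * N_COLUMNS + (self.column - 1)


def parse_well(text: str) -> WellId:
    """Parse a well name such as ``"A01"``, ``"a1"`` or ``"H12"``.

    The row letter is case-insensitive and the column may be written with or
    without a leading zero; ``parse_well("A1") == parse_well("A01")``.

    Raises
    ------
    ValidationError
        If the text is empty, malformed, or names a row/column outside the
        8 x 12 plate.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValidationError(f"empty or non-text well name: {text!r}")
    token = text.strip()
    row, rest = token[0].upper(), token[1:]
    if not rest.isdigit():
        raise ValidationError(f"malformed well name {token!r}")
    if row not in ROW_LETTERS:
        raise ValidationError(f"well row of {token!r} outside A-H")
    column = int(rest)
    if not (1 <= column <= N_COLUMNS):
        raise ValidationError(f"well column of {token!r} outside 1-12")
    return WellId(row, column)


def all_wells() -> list[WellId]:
    """The 96 wells of a plate in row-major order (A01, A02, .., H12)."""
    return [
        WellId(r, c) for r in ROW_LETTERS for c in range(1, N_COLUMNS + 1)
    ]


def condition_key(
    factors: Mapping[str, str],
    separator: str = DEFAULT_SEPARATOR,
    factor_names: Sequence[str] | None = None,
) -> str:
    """Join a row's factor labels into a single condition label.

    Labels are joined in ``factor_names`` order when given (the declared
    column order of the design), otherwise in the mapping's insertion order.
    The same factors presented in a permuted order therefore yield the same
    key as long as the declared order is supplied.

    A label that itself contains the separator makes distinct factor tuples
    collide onto one key; this is reported as a
    :class:`SeparatorCollisionWarning`, not an error.
    """
    if not factors:
        raise ValidationError("condition_key requires at least one factor")
    names = list(factor_names) if factor_names is not None else list(factors)
    if set(names) != set(factors):
        raise ValidationError(
            f"factor_names {names} do not match factors {sorted(factors)}"
        )
    labels = [str(factors[name]) for name in names]
    for lab in labels:
        if separator in lab:
            warnings.warn(
                f"factor label {lab!r} contains the separator {separator!r}; "
                "condition keys may collide",
                SeparatorCollisionWarning,
                stacklevel=2,
            )
    return separator.join(labels)


def _canonical_well_column(values: Iterable) -> list[str]:
    return [parse_well(str(v)).text for v in values]


def _check_signal(values: pd.Series, name: str, allow_negative: bool) -> None:
    arr = pd.to_numeric(values, errors="coerce")
    bad = values[arr.isna()]
    if len(bad):
        raise ValidationError(
            f"non-numeric {name} values at rows {list(bad.index[:5])}"
        )
    if not np.isfinite(arr.to_numpy(dtype=float)).all():
        raise ValidationError(f"non-finite {name} values present")
    if not allow_negative and (arr < 0).any():
        wells = list(values.index[arr < 0])[:5]
        raise ValidationError(
            f"negative {name} values (rows {wells}); luminescence counts "
            "must be >= 0 (pass allow_negative=True to accept "
            "background-subtracted data)"
        )


@dataclass(eq=False)
class PlateReadings:
    """Paired firefly/renilla luminescence for one 96-well plate.

    ``data`` holds one row per measured well with columns ``well`` (canonical
    name), ``firefly`` and ``renilla`` (counts, arbitrary units).  Both
    channels must be present for every well — a missing channel is a parse
    error upstream, never a silent gap here.
    """

    data: pd.DataFrame
    plate_id: str = "plate"
    allow_negative: bool = False

    def __post_init__(self) -> None:
        required = {"well", "firefly", "renilla"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"PlateReadings missing columns {missing}")
        df = self.data.reset_index(drop=True).copy()
        df["well"] = _canonical_well_column(df["well"])
        dupes = df["well"][df["well"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate wells on plate: {dupes}")
        if len(df) > PLATE_SIZE:
            raise ValidationError(f"{len(df)} wells exceed plate size 96")
        for channel in ("firefly", "renilla"):
            _check_signal(df[channel], channel, self.allow_negative)
            df[channel] = df[channel].astype(float)
        self.data = df[["well", "firefly", "renilla"]]

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "PlateReadings", tol: float = 1e-9) -> bool:
        """Same wells and channel values within absolute/relative ``tol``."""
        a = self.data.sort_values("well").reset_index(drop=True)
        b = other.data.sort_values("well").reset_index(drop=True)
        if list(a["well"]) != list(b["well"]):
            return False
        return bool(
            np.allclose(a[["firefly", "renilla"]], b[["firefly", "renilla"]],
                        rtol=tol, atol=tol)
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PlateReadings) and self.equals(other)


@dataclass(eq=False)
class DesignTable:
    """Per-well experimental factor assignments.

    ``data`` has a canonical ``well`` column plus one column per factor in
    ``factor_names`` (file column order).  Every row carries a non-empty
    label for every factor.
    """

    data: pd.DataFrame
    factor_names: list[str]

    def __post_init__(self) -> None:
        if not self.factor_names:
            raise ValidationError("design has no factor columns")
        if len(set(self.factor_names)) != len(self.factor_names):
            raise ValidationError(
                f"duplicate factor names: {self.factor_names}"
            )
        missing = {"well", *self.factor_names} - set(self.data.columns)
        if missing:
            raise ValidationError(f"design missing columns {missing}")
        df = self.data.reset_index(drop=True).copy()
        df["well"] = _canonical_well_column(df["well"])
        dupes = df["well"][df["well"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate wells in design: {dupes}")
        for name in self.factor_names:
            if not name.strip():
                raise ValidationError("empty factor name in design")
            df[name] = df[name].astype(str).str.strip()
            if (df[name] == "").any():
                raise ValidationError(f"empty labels in factor {name!r}")
        self.data = df[["well", *self.factor_names]]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(eq=False)
class TidyExperiment:
    """The merged analysis table: one observation (well) per row.

    Columns of ``data``: ``well``, one column per factor, ``firefly``,
    optionally ``renilla``, and — once computed — ``ratio`` and
    ``fold_change``.  The renilla internal control is either present for all
    rows or absent entirely; a mixed column is invalid.  ``reference`` records
    the condition selector used for fold-change normalization, if any.
    """

    data: pd.DataFrame
    factor_names: list[str]
    separator: str = DEFAULT_SEPARATOR
    reference: str | None = None
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if not self.factor_names:
            raise ValidationError("experiment has no factor columns")
        missing = {"well", "firefly", *self.factor_names} - set(
            self.data.columns
        )
        if missing:
            raise ValidationError(f"experiment missing columns {missing}")
        df = self.data.reset_index(drop=True).copy()
        df["well"] = _canonical_well_column(df["well"])
        dupes = df["well"][df["well"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate wells in experiment: {dupes}")
        _check_signal(df["firefly"], "firefly", self.allow_negative)
        df["firefly"] = df["firefly"].astype(float)
        if "renilla" in df.columns:
            n_missing = df["renilla"].isna().sum()
            if n_missing == len(df):
                df = df.drop(columns="renilla")
            elif n_missing > 0:
                raise ValidationError(
                    "renilla present for some rows but missing for "
                    f"{n_missing}; the control channel must be all-present "
                    "or absent"
                )
            else:
                _check_signal(df["renilla"], "renilla", self.allow_negative)
                df["renilla"] = df["renilla"].astype(float)
        for name in self.factor_names:
            df[name] = df[name].astype(str)
        ordered = ["well", *self.factor_names, "firefly"]
        for extra in ("renilla", "ratio", "fold_change"):
            if extra in df.columns:
                df[extra] = df[extra].astype(float)
                ordered.append(extra)
        self.data = df[ordered]

    # -- convenience accessors -------------------------------------------

    @property
    def has_renilla(self) -> bool:
        return "renilla" in self.data.columns

    @property
    def has_ratio(self) -> bool:
        return "ratio" in self.data.columns

    @property
    def has_fold_change(self) -> bool:
        return "fold_change" in self.data.columns

    def __len__(self) -> int:
        return len(self.data)

    def condition_keys(self) -> pd.Series:
        """Per-row condition label: factor values joined by ``separator``."""
        parts = self.data[self.factor_names].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparatorCollisionWarning)
            keys = parts.apply(
                lambda row: condition_key(
                    dict(row), self.separator, self.factor_names
                ),
                axis=1,
            )
        return keys.rename("condition")

    def replace_data(self, data: pd.DataFrame) -> "TidyExperiment":
        """New experiment with the same metadata and different rows."""
        return TidyExperiment(
            data=data,
            factor_names=list(self.factor_names),
            separator=self.separator,
            reference=self.reference,
            allow_negative=self.allow_negative,
        )

    def equals(self, other: "TidyExperiment", tol: float = 1e-9) -> bool:
        a = self.data.sort_values("well").reset_index(drop=True)
        b = other.data.sort_values("well").reset_index(drop=True)
        if list(a.columns) != list(b.columns):
            return False
        if list(a["well"]) != list(b["well"]):
            return False
        text_cols = ["well", *self.factor_names]
        if not a[text_cols].equals(b[text_cols]):
            return False
        num_cols = [c for c in a.columns if c not in text_cols]
        return bool(
            np.allclose(a[num_cols], b[num_cols], rtol=tol, atol=tol,
                        equal_nan=True)
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TidyExperiment) and self.equals(other)


@dataclass(eq=False)
class SummaryTable:
    """Per-condition descriptive statistics of the ratio or fold change.

    One row per distinct condition key with ``n``, ``mean``, ``sd`` (sample,
    n-1 denominator), ``sem``, ``median`` and the 95% t-interval bounds of
    the mean.  Dispersion statistics are NaN (unset) for n = 1.
    """

    data: pd.DataFrame
    value: str = "fold_change"

    COLUMNS = (
        "condition", "n", "mean", "sd", "sem", "median",
        "ci95_low", "ci95_high",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"summary missing columns {missing}")
        if (self.data["n"] < 1).any():
            raise ValidationError("summary rows with n < 1")
        if self.data["condition"].duplicated().any():
            raise ValidationError("duplicate condition rows in summary")
        self.data = self.data.reset_index(drop=True)[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.data)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_text(self) -> str:
        """Plain-text rendering of the table (fixed-width columns)."""
        shown = self.data.copy()
        for col in shown.columns:
            if shown[col].dtype.kind == "f":
                shown[col] = shown[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.4g}"
                )
        return shown.to_string(index=False)

    def write_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"summary of {self.value}\n")
            fh.write(self.to_text())
            fh.write("\n")


def parse_reference(selector: str) -> tuple[str | None, str]:
    """Split a reference selector into ``(factor, level)`` or ``(None, key)``.

    Selectors come in two forms: ``"factor=level"`` names a level of a single
    factor (required for stratified normalization); any other string is taken
    as a full condition key.
    """
    if not selector or not str(selector).strip():
        raise ValidationError("empty reference selector")
    selector = str(selector).strip()
    if "=" in selector:
        factor, _, level = selector.partition("=")
        if not factor.strip() or not level.strip():
            raise ValidationError(
                f"malformed reference selector {selector!r}; expected "
                "'factor=level' or a full condition key"
            )
        return factor.strip(), level.strip()
    return None, selector


@dataclass
class NormalizationConfig:
    """How the fold-change denominator is chosen.

    ``reference`` is a condition selector (``"factor=level"`` or a full
    condition key).  ``stratified=None`` picks the mode automatically: rows
    are partitioned by the non-reference factors whenever the experiment has
    more than one factor and the selector names a single factor level,
    otherwise a single global denominator is used.  ``geometric`` switches
    the reference average from the arithmetic to the geometric mean.
    """

    reference: str
    stratified: bool | None = None
    show_reference: bool = True
    geometric: bool = False

    def __post_init__(self) -> None:
        factor, _ = parse_reference(self.reference)
        if self.stratified is True and factor is None:
            raise ValidationError(
                "stratified normalization needs a 'factor=level' reference "
                f"selector, got {self.reference!r}"
            )
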