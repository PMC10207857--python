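"""Schema-aware categorical record tables and preprocessing.

A registry record table is a rectangular grid of categorical tokens: one row
per tumor record, one column per variable, every cell drawn from the
variable's declared domain.  Three preprocessing steps are provided, matching
how cancer registries prepare diagnostic records before plausibility
screening: equal-count binning of numeric variables (age at diagnosis, age at
death), filling missing cells with a reserved sentinel token so incomplete
records stay in the analysis, and exact-duplicate removal over the full
variable set.

The missing sentinel is an ordinary category downstream: it participates in
pattern mining and one-hot encoding like any other token.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved token substituted for missing cells.
MISSING_TOKEN = "MISSING"

#: Cell values treated as missing on input (empty cell or pandas NA).
_MISSING_INPUTS = ("", None)


class SchemaViolationError(ValueError):
    """A cell token is not in the declared domain of its variable."""


class ParseError(ValueError):
    """A delimited-text file is malformed (ragged rows, missing header)."""


class BinningError(ValueError):
    """Equal-count binning is degenerate for the requested bin count."""


@dataclass(frozen=True)
class VariableSchema:
    """One categorical variable: a name and an ordered domain of tokens."""

    name: str
    domain: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.domain) == 0:
            raise ValueError(f"variable {self.name!r}: domain must be non-empty")
        if len(set(self.domain)) != len(self.domain):
            raise ValueError(f"variable {self.name!r}: domain has duplicate tokens")
        object.__setattr__(self, "domain", tuple(str(t) for t in self.domain))

    def __contains__(self, token: str) -> bool:
        return token in self.domain

    @property
    def size(self) -> int:
        return len(self.domain)


@dataclass
class RecordTable:
    """Rows of categorical records under a declared variable schema.

    ``data`` is a string-dtype DataFrame whose columns follow schema order and
    whose index carries stable integer row identifiers.  Empty-string cells
    denote missing values and are only legal until :func:`fill_missing` runs.
    """

    schema: list[VariableSchema]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [v.name for v in self.schema]
        if list(self.data.columns) != names:
            self.data = self.data.loc[:, names]
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.schema]

    @property
    def row_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def schema_for(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def row(self, row_id) -> dict[str, str]:
        """One record as a variable → token mapping."""
        return self.data.loc[row_id].to_dict()

    def iter_rows(self) -> Iterable[tuple[int, dict[str, str]]]:
        for row_id, row in self.data.iterrows():
            yield row_id, row.to_dict()

    def codes(self) -> np.ndarray:
        """Integer-coded matrix (n_rows × n_vars); code = index in the domain."""
        cols = []
        for v in self.schema:
            cat = pd.Categorical(self.data[v.name], categories=list(v.domain))
            if (cat.codes < 0).any():
                bad = self.data[v.name][cat.codes < 0].iloc[0]
                raise SchemaViolationError(
                    f"variable {v.name!r}: token {bad!r} outside domain"
                )
            cols.append(cat.codes.astype(np.int32))
        return np.column_stack(cols)

    def validate(self) -> None:
        for v in self.schema:
            col = self.data[v.name]
            allowed = set(v.domain) | {""}
            bad = col[~col.isin(allowed)]
            if len(bad):
                row_id = bad.index[0]
                raise SchemaViolationError(
                    f"variable {v.name!r}, row {row_id}: token {bad.iloc[0]!r} "
                    f"not in domain"
                )

    def copy(self) -> "RecordTable":
        return RecordTable([*self.schema], self.data.copy())

    def subset(self, row_ids) -> "RecordTable":
        return RecordTable([*self.schema], self.data.loc[list(row_ids)].copy())


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def read_records(
    path,
    schema: Sequence[VariableSchema] | None = None,
    delimiter: str = ",",
) -> RecordTable:
    """Read a delimited-text record table (header row required).

    If ``schema`` is omitted, each variable's domain is inferred as the sorted
    set of observed tokens in its column (empty cells excluded).  If a schema
    is supplied and the header names match the schema names as a set, columns
    are matched by name; otherwise they are taken positionally in schema
    order.  Tokens outside a supplied domain raise :class:`SchemaViolationError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header row required") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)

    df = pd.DataFrame(rows, columns=header, dtype=str)
    df.index = pd.RangeIndex(len(df))

    if schema is not None:
        schema = list(schema)
        names = [v.name for v in schema]
        if set(header) == set(names):
            df = df.loc[:, names]
        elif len(header) == len(names):
            df.columns = names
        else:
            raise ParseError(
                f"{path}: {len(header)} columns cannot be matched to "
                f"{len(names)}-variable schema"
            )
        return RecordTable(schema, df)

    inferred = []
    for name in df.columns:
        tokens = sorted(set(df[name]) - {""})
        if not tokens:
            tokens = [MISSING_TOKEN]
        inferred.append(VariableSchema(name, tuple(tokens)))
    return RecordTable(inferred, df)


def write_records(table: RecordTable, path, delimiter: str = ",") -> None:
    """Write a record table as delimited text with a header row."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(table.variables)
        for _, row in table.data.iterrows():
            writer.writerow([row[v] for v in table.variables])


def read_schema(path) -> list[VariableSchema]:
    """Read a schema file: JSON ``{"variables": [{"name":…, "domain":[…]}]}``."""
    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        VariableSchema(v["name"], tuple(v["domain"])) for v in payload["variables"]
    ]


def write_schema(schema: Sequence[VariableSchema], path) -> None:
    payload = {
        "variables": [{"name": v.name, "domain": list(v.domain)} for v in schema]
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _fmt_edge(x: float) -> str:
    if math.isfinite(x) and float(x) == int(x):
        return str(int(x))
    return f"{x:g}"


def bin_equal_count(
    values: Sequence[float], n_bins: int
) -> tuple[list[str], list[str]]:
    """Equal-count (quantile) binning of a numeric sequence.

    Cut points are the empirical ``i/n_bins`` quantiles.  Bins are half-open
    ``[lo,hi)`` with the last bin closed on the right; a value equal to a cut
    point goes to the upper bin.  Returns ``(labels_per_value, bin_labels)``.

    Raises :class:`BinningError` when ``n_bins`` exceeds the number of
    distinct values (no equal-count assignment exists).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise BinningError("cannot bin an empty sequence")
    if n_bins < 1:
        raise BinningError("n_bins must be >= 1")
    n_distinct = np.unique(arr).size
    if n_bins > n_distinct:
        raise BinningError(
            f"n_bins={n_bins} exceeds {n_distinct} distinct values"
        )

    interior = np.quantile(arr, np.arange(1, n_bins) / n_bins)
    lo, hi = arr.min(), arr.max()
    bounds = np.concatenate(([lo], interior, [hi]))
    bin_labels = []
    for i in range(n_bins):
        close = "]" if i == n_bins - 1 else ")"
        bin_labels.append(f"[{_fmt_edge(bounds[i])},{_fmt_edge(bounds[i + 1])}{close}")
    # value == cut point -> upper bin (half-open membership)
    idx = np.searchsorted(interior, arr, side="right")
    labels = [bin_labels[i] for i in idx]
    return labels, bin_labels


def fill_missing(table: RecordTable, sentinel: str = MISSING_TOKEN) -> RecordTable:
    """Replace missing (empty) cells with a reserved sentinel token.

    The sentinel is appended to every variable's domain when absent, so it is
    a first-class category for pattern mining and one-hot encoding.
    Non-missing cells are never altered.
    """
    new_schema = []
    for v in table.schema:
        domain = v.domain if sentinel in v.domain else (*v.domain, sentinel)
        new_schema.append(VariableSchema(v.name, domain))
    data = table.data.copy()
    data = data.mask(data.isin(list(_MISSING_INPUTS)) | data.isna(), sentinel)
    return RecordTable(new_schema, data)


def deduplicate(table: RecordTable) -> RecordTable:
    """Drop exact-duplicate rows over all variables, keeping first occurrences.

    Surviving rows keep their original row identifiers and relative order.
    """
    data = table.data[~table.data.duplicated(keep="first")].copy()
    return RecordTable([*table.schema], data)
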