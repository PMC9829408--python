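"""Input model: the point table and the optional sparse-override list.

The minimum input for a hatched scatter plot is a table of x, y coordinates
plus one categorical column naming the cell group (cluster, cell type,
microscopy frame, ...).  This module loads and validates that table from
delimited text and round-trips it back out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoordinateParseError,
    EmptyInputError,
    InputSchemaError,
    UnknownIdError,
)

__all__ = [
    "PointTable",
    "SparseOverride",
    "load_point_table",
    "write_point_table",
    "load_sparse_override",
]


@dataclass(frozen=True)
class PointTable:
    """Ordered collection of (id, x, y, group) point records.

    Parameters
    ----------
    ids
        Unique per-point keys (strings or integers).  Default to the 0-based
        row index when the source table has no id column.
    x, y
        Finite coordinates in data units (embedding axes or spatial microns).
    group
        Categorical label per point; compared as exact strings after
        whitespace trimming (no case folding, so biologically distinct labels
        are never merged silently).
    """

    ids: tuple
    x: np.ndarray
    y: np.ndarray
    group: tuple

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(
            self, "group", tuple(str(g).strip() for g in self.group)
        )
        n = len(self.ids)
        if n == 0:
            raise EmptyInputError("point table contains no records")
        if not (len(x) == len(y) == len(self.group) == n):
            raise InputSchemaError("ids, x, y and group must have equal length")
        if len(set(self.ids)) != n:
            raise InputSchemaError("point ids are not unique")
        bad = ~(np.isfinite(x) & np.isfinite(y))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CoordinateParseError(
                f"non-finite coordinate at row {row} (id {self.ids[row]!r})"
            )

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PointTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.group == other.group
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def groups(self) -> list:
        """Distinct group labels in first-appearance order."""
        seen: dict = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def group_indices(self, label) -> np.ndarray:
        """Integer row indices of the points belonging to ``label``."""
        grp = np.asarray(self.group, dtype=object)
        return np.flatnonzero(grp == label)

    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax) of all points."""
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.ids), "x": self.x, "y": self.y, "group": list(self.group)}
        )


@dataclass(frozen=True)
class SparseOverride:
    """Set of point ids the user forces to be treated as sparse.

    Bypasses the built-in sparse point detector entirely: listed points are
    labelled sparse, every other point dense.
    """

    ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(self.ids))

    def validate_against(self, points: PointTable) -> None:
        known = set(points.ids)
        for i in sorted(self.ids, key=str):
            if i not in known:
                raise UnknownIdError(
                    f"sparse-override id {i!r} does not exist in the point table"
                )


def _detect_delimiter(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def load_point_table(
    path,
    x_field: str = "x",
    y_field: str = "y",
    group_field: str = "group",
    id_field: str | None = None,
    delimiter: str | None = None,
) -> PointTable:
    """Load a delimited text table into a validated :class:`PointTable`.

    The delimiter is inferred from the extension (``.csv`` comma, anything
    else tab) unless given explicitly.  Row order is preserved exactly; ids
    default to the 0-based row index when ``id_field`` is None.
    """
    if not os.path.exists(path):
        raise InputSchemaError(f"input file not found: {path}")
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise EmptyInputError(f"input table {path} has no data rows")
    for col in (x_field, y_field, group_field):
        if col not in df.columns:
            raise InputSchemaError(
                f"required column {col!r} not found (columns: {list(df.columns)})"
            )
    if id_field is not None and id_field not in df.columns:
        raise InputSchemaError(f"id column {id_field!r} not found")

    coords = {}
    for col in (x_field, y_field):
        raw = df[col].tolist()
        vals = np.empty(len(raw), dtype=float)
        for row, s in enumerate(raw):
            try:
                vals[row] = float(s)  # correctly-rounded, full precision
            except ValueError:
                vals[row] = np.nan
            if not np.isfinite(vals[row]):
                raise CoordinateParseError(
                    f"column {col!r}, row {row}: value {s!r} "
                    "is not a finite number"
                )
        coords[col] = vals

    if id_field is not None:
        raw = df[id_field].tolist()
        # numeric-looking id columns round-trip as integers
        ids = []
        for v in raw:
            try:
                ids.append(int(v))
            except ValueError:
                ids.append(v)
    else:
        ids = list(range(len(df)))

    return PointTable(
        ids=tuple(ids),
        x=coords[x_field],
        y=coords[y_field],
        group=tuple(df[group_field].tolist()),
    )


def write_point_table(table: PointTable, path, delimiter: str | None = None) -> None:
    """Write a PointTable back to delimited text (full-precision round trip)."""
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    df = table.to_frame()
    df["x"] = [repr(float(v)) for v in table.x]
    df["y"] = [repr(float(v)) for v in table.y]
    df.to_csv(path, sep=sep, index=False)


def load_sparse_override(path) -> SparseOverride:
    """Read a sparse-override file: one point id per line, blanks ignored."""
    if not os.path.exists(path):
        raise InputSchemaError(f"sparse-override file not found: {path}")
    ids = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if not tok:
                continue
            try:
                ids.append(int(tok))
            except ValueError:
                ids.append(tok)
    return SparseOverride(ids=frozenset(ids))
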