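"""Reading, validating, pooling and writing hook-measurement tables.

The input dialect is a plain comma-separated file with the exact header
``specimen,hook,length,base``: one row per hook, hooks numbered from the
distal end of the proboscis (1-based), blade length and base width in
micrometres.  Sex and proboscis surface (dorsal/ventral) apply to a whole
file and are supplied by the caller when reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HookRecord",
    "HookRow",
    "HookCollection",
    "FormatError",
    "IntegrityError",
    "read_hook_csv",
    "merge_collections",
    "write_meristogram_csv",
    "read_meristogram_csv",
]

logger = logging.getLogger(__name__)

HOOK_HEADER = ("specimen", "hook", "length", "base")

SEXES = ("female", "male", "unknown")
SURFACES = ("dorsal", "ventral", "unknown")


class FormatError(ValueError):
    """Malformed input file (wrong header, empty file, unparseable cells)."""


class IntegrityError(ValueError):
    """Structurally valid file whose content violates row-level invariants."""


@dataclass(frozen=True)
class HookRecord:
    """One hook: ordinal position in the row (distal end = 1) and its two
    measured dimensions in µm."""

    ordinal: int
    length: float
    base: float

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError(f"hook ordinal must be >= 1, got {self.ordinal}")
        if not self.length > 0:
            raise ValueError(f"hook length must be positive, got {self.length}")
        if not self.base > 0:
            raise ValueError(f"hook base must be positive, got {self.base}")


@dataclass(frozen=True)
class HookRow:
    """One specimen's longitudinal row of hooks, ordered distal to proximal."""

    specimen: str
    records: tuple[HookRecord, ...]
    sex: str = "unknown"
    surface: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.surface not in SURFACES:
            raise ValueError(
                f"surface must be one of {SURFACES}, got {self.surface!r}"
            )
        ordinals = [r.ordinal for r in self.records]
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise IntegrityError(
                f"specimen {self.specimen!r}: hook ordinals must be exactly "
                f"1..n with no gaps or duplicates, got {ordinals}"
            )
        if self.n < 1:
            raise IntegrityError(f"specimen {self.specimen!r}: empty hook row")

    @property
    def n(self) -> int:
        """Number of hooks in the row."""
        return len(self.records)


@dataclass(frozen=True)
class HookCollection:
    """A labelled set of hook rows pooled for one meristogram."""

    label: str
    rows: tuple[HookRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"collection {self.label!r} has no rows")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_hooks(self) -> int:
        return sum(r.n for r in self.rows)

    @property
    def min_row_length(self) -> int:
        """Hook count of the shortest row (drives the minimum smoothing window)."""
        return min(r.n for r in self.rows)

    def relabel(self, label: str) -> "HookCollection":
        return replace(self, label=label)


def read_hook_csv(
    path: str | Path,
    *,
    sex: str = "unknown",
    surface: str = "unknown",
    label: str | None = None,
) -> HookCollection:
    """Read a four-column hook table into a :class:`HookCollection`.

    One :class:`HookRow` is produced per distinct ``specimen`` value, with
    records sorted by ordinal.  ``sex`` and ``surface`` tag every row of the
    file, mirroring the one-file-per-sex(-per-surface) layout of published
    hook datasets.

    Raises
    ------
    FormatError
        Header does not match ``specimen,hook,length,base`` or the file is
        unparseable.
    IntegrityError
        Duplicate (specimen, ordinal) pairs, or ordinals of some specimen do
        not form a gapless 1..n sequence.
    ValueError
        Non-numeric or non-positive length/base values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skip_blank_lines=True, dtype={"specimen": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if tuple(df.columns) != HOOK_HEADER:
        raise FormatError(
            f"{path}: header must be exactly {','.join(HOOK_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    for col in ("hook", "length", "base"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad = df.loc[numeric.isna()].iloc[0]
            raise ValueError(
                f"{path}: non-numeric {col} for specimen {bad['specimen']!r}"
            )
        df[col] = numeric

    if (df["length"] <= 0).any() or (df["base"] <= 0).any():
        bad = df.loc[(df["length"] <= 0) | (df["base"] <= 0)].iloc[0]
        raise ValueError(
            f"{path}: non-positive measurement for specimen "
            f"{bad['specimen']!r}, hook {int(bad['hook'])}"
        )

    dup = df.duplicated(subset=["specimen", "hook"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate hook ordinal {int(bad['hook'])} for specimen "
            f"{bad['specimen']!r}"
        )

    rows = []
    # sort_values inside each group: the reader is insensitive to line order
    for specimen, grp in sorted(df.groupby("specimen", sort=False)):
        grp = grp.sort_values("hook")
        records = tuple(
            HookRecord(ordinal=int(h), length=float(l), base=float(b))
            for h, l, b in zip(grp["hook"], grp["length"], grp["base"])
        )
        ordinals = [r.ordinal for r in records]
        if ordinals != list(range(1, len(records) + 1)):
            raise IntegrityError(
                f"{path}: specimen {specimen!r} ordinals {ordinals} do not "
                f"form 1..{len(records)}"
            )
        if len(records) < 3:
            logger.warning(
                "%s: specimen %r has only %d hook(s); smoothing will be weak",
                path,
                specimen,
                len(records),
            )
        rows.append(
            HookRow(specimen=str(specimen), records=records, sex=sex, surface=surface)
        )

    return HookCollection(label=label if label is not None else path.stem, rows=tuple(rows))


def merge_collections(parts: Sequence[HookCollection], label: str) -> HookCollection:
    """Pool several collections (e.g. per-sex or per-surface files) under one
    label.

    Rows are concatenated verbatim: the same specimen may legitimately
    contribute both a dorsal and a ventral row, and those stay distinct.
    """
    if not parts:
        raise ValueError("merge_collections requires at least one collection")
    rows: list[HookRow] = []
    for part in parts:
        rows.extend(part.rows)
    return HookCollection(label=label, rows=tuple(rows))


def write_meristogram_csv(m, path: str | Path) -> None:
    """Write a computed meristogram as ``position,L,B,A,R`` with 6 significant
    digits per value."""
    if not m.points:
        raise ValueError("cannot write an empty meristogram")
    path = Path(path)
    frame = m.to_frame()
    frame.to_csv(path, index=False, float_format="%.6g")


def read_meristogram_csv(path: str | Path) -> pd.DataFrame:
    """Read back a ``position,L,B,A,R`` table written by
    :func:`write_meristogram_csv`."""
    df = pd.read_csv(path)
    expected = ["position", "L", "B", "A", "R"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: header must be {','.join(expected)}, got {','.join(df.columns)}"
        )
    return df
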