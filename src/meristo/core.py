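"""The meristogram algorithm.

A meristogram summarises serial variation in hook morphology along the
acanthocephalan proboscis as four smoothed, doubly standardized curves:

* **L** — blade length,
* **B** — base width,
* **A** — triangular area estimate, length × base / 2,
* **R** — robustness ("stoutness") ratio, base × 100 / length,

each plotted against percent-position along the hook row.  The pipeline is

1. *position standardization* — ordinal i in a row of n hooks maps to
   i·100/(n+1), so rows of different length become comparable (the +1
   centres the points in (0, 100));
2. *derived variables* — A and R computed per hook;
3. *row standardization* — L, B, A, R each expressed as a percentage of
   their own maximum within the row, removing absolute size (and with it
   sexual size dimorphism and other allometry);
4. *moving average* — a window of width w percent slides along the
   percent-position axis in 1 % steps; each placement containing hooks
   yields one point whose abscissa is the mean hook position and whose
   ordinates are the mean standardized variables;
5. *(optional) linear interpolation* onto the integer percent-position
   grid, which gives every collection a common abscissa for multivariate
   comparison;
6. *collection rescaling* — each smoothed curve divided by its own maximum
   and ×100 ("percent-max-collection-value"), so every curve tops out at
   exactly 100.

The minimum admissible window (MMAI) is ceil(100/(nmin+1)) where nmin is
the hook count of the shortest row: it guarantees that every specimen
contributes to every window placement in the populated part of the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hookio import HookCollection, HookRecord, HookRow

__all__ = [
    "VARIABLES",
    "StandardizedHook",
    "CurvePoint",
    "Meristogram",
    "standardize_positions",
    "derive_variables",
    "standardize_row",
    "minimum_mai",
    "moving_average",
    "interpolate_curves",
    "rescale_to_collection_max",
    "compute_meristogram",
    "peak_positions",
]

VARIABLES = ("L", "B", "A", "R")


@dataclass(frozen=True)
class StandardizedHook:
    """One hook after position and row standardization.

    ``p`` is the percent-position in (0, 100); ``l``, ``b``, ``a``, ``r``
    are percentages of the row maximum of each variable, in (0, 100].
    """

    p: float
    l: float
    b: float
    a: float
    r: float


@dataclass(frozen=True)
class CurvePoint:
    """One smoothed point: mean percent-position of the hooks in a window and
    the four mean (or rescaled) variable values."""

    x: float
    L: float
    B: float
    A: float
    R: float

    def values(self) -> tuple[float, float, float, float]:
        return (self.L, self.B, self.A, self.R)


@dataclass(frozen=True)
class Meristogram:
    """Four standardized, smoothed curves over percent-position.

    After rescaling, each of L, B, A, R attains a maximum of exactly 100
    somewhere on the curve.  ``provenance`` records the number of rows and
    hooks pooled.
    """

    label: str
    mai: int
    interpolated: bool
    points: tuple[CurvePoint, ...]
    provenance: Mapping[str, int] = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return np.array([pt.x for pt in self.points])

    def curve(self, variable: str) -> np.ndarray:
        if variable not in VARIABLES:
            raise KeyError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
        return np.array([getattr(pt, variable) for pt in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.x,
                "L": self.curve("L"),
                "B": self.curve("B"),
                "A": self.curve("A"),
                "R": self.curve("R"),
            }
        )


def standardize_positions(row: HookRow) -> list[float]:
    """Percent-positions i·100/(n+1) for i = 1..n."""
    n = row.n
    return [rec.ordinal * 100.0 / (n + 1) for rec in row.records]


def derive_variables(rec: HookRecord) -> tuple[float, float]:
    """Area (µm², triangular approximation) and robustness ratio of one hook.

    area = length·base/2; ratio = base·100/length.
    """
    if not rec.length > 0:
        raise ValueError(f"hook length must be positive, got {rec.length}")
    return rec.length * rec.base / 2.0, rec.base * 100.0 / rec.length


def standardize_row(row: HookRow) -> list[StandardizedHook]:
    """Standardize one row: percent-positions plus each variable as a
    percentage of its own row maximum.

    The four maxima are taken independently and may fall on different hooks.
    """
    positions = standardize_positions(row)
    lengths = np.array([rec.length for rec in row.records])
    bases = np.array([rec.base for rec in row.records])
    areas = lengths * bases / 2.0
    ratios = bases * 100.0 / lengths
    out = []
    for p, l, b, a, r in zip(
        positions,
        lengths * 100.0 / lengths.max(),
        bases * 100.0 / bases.max(),
        areas * 100.0 / areas.max(),
        ratios * 100.0 / ratios.max(),
    ):
        out.append(StandardizedHook(p=p, l=float(l), b=float(b), a=float(a), r=float(r)))
    return out


def minimum_mai(c: HookCollection) -> int:
    """Minimum moving-average interval: ceil(100/(nmin+1)) percent, nmin the
    hook count of the shortest row.

    With any window at least this wide, every specimen is represented in
    every window placement over the populated span of the axis.
    """
    return math.ceil(100.0 / (c.min_row_length + 1))


def _standardize_collection(c: HookCollection) -> list[StandardizedHook]:
    hooks: list[StandardizedHook] = []
    for row in c.rows:
        hooks.extend(standardize_row(row))
    return hooks


def moving_average(
    hooks: Sequence[StandardizedHook], w: int, *, mmai: int | None = None
) -> list[CurvePoint]:
    """Slide a half-open window [s, s+w) over s = 0, 1, …, 100−w and emit one
    point per non-empty placement.

    The point's abscissa is the mean percent-position of the hooks in the
    window, not the window midpoint — hence the characteristically
    non-uniform point spacing of unsmoothed meristograms.  Consecutive
    placements covering the identical hook set collapse to one point.
    """
    if not hooks:
        raise ValueError("no hooks to smooth")
    if int(w) != w:
        raise ValueError(f"moving-average interval must be an integer percent, got {w}")
    w = int(w)
    if w > 100:
        raise ValueError(f"moving-average interval cannot exceed 100, got {w}")
    if mmai is not None and w < mmai:
        raise ValueError(
            f"moving-average interval {w}% is below the minimum admissible "
            f"interval {mmai}% for this collection"
        )

    p = np.array([h.p for h in hooks])
    vals = np.array([[h.l, h.b, h.a, h.r] for h in hooks])

    points: list[CurvePoint] = []
    prev_members: frozenset[int] | None = None
    for s in range(0, 101 - w):
        members = frozenset(np.flatnonzero((p >= s) & (p < s + w)).tolist())
        if not members or members == prev_members:
            prev_members = members or prev_members
            continue
        prev_members = members
        idx = sorted(members)
        L, B, A, R = vals[idx].mean(axis=0)
        points.append(
            CurvePoint(x=float(p[idx].mean()), L=float(L), B=float(B), A=float(A), R=float(R))
        )

    points.sort(key=lambda pt: pt.x)
    # distinct hook sets can coincide in mean position; keep the first
    deduped: list[CurvePoint] = []
    for pt in points:
        if deduped and pt.x == deduped[-1].x:
            continue
        deduped.append(pt)
    return deduped


def interpolate_curves(points: Sequence[CurvePoint]) -> list[CurvePoint]:
    """Resample all four curves at every integer percent-position inside the
    span of the input, by piecewise-linear interpolation.

    No extrapolation: the grid is [ceil(xmin), floor(xmax)].
    """
    xs = np.array([pt.x for pt in points])
    if len(np.unique(xs)) < 2:
        raise ValueError(
            "interpolation needs at least two points with distinct positions; "
            "disable interpolation for this collection"
        )
    grid = np.arange(math.ceil(xs[0]), math.floor(xs[-1]) + 1)
    out: list[CurvePoint] = []
    curves = {
        v: np.interp(grid, xs, np.array([getattr(pt, v) for pt in points]))
        for v in VARIABLES
    }
    for i, x in enumerate(grid):
        out.append(
            CurvePoint(
                x=float(x),
                L=float(curves["L"][i]),
                B=float(curves["B"][i]),
                A=float(curves["A"][i]),
                R=float(curves["R"][i]),
            )
        )
    return out


def rescale_to_collection_max(points: Sequence[CurvePoint]) -> list[CurvePoint]:
    """Scale each variable independently so its maximum over the curve is 100
    (the percent-max-collection-value)."""
    if not points:
        raise ValueError("no points to rescale")
    arr = np.array([[pt.L, pt.B, pt.A, pt.R] for pt in points])
    scaled = arr * (100.0 / arr.max(axis=0))
    return [
        CurvePoint(x=pt.x, L=float(row[0]), B=float(row[1]), A=float(row[2]), R=float(row[3]))
        for pt, row in zip(points, scaled)
    ]


def compute_meristogram(
    c: HookCollection, w: int | None = None, *, interpolate: bool = True
) -> Meristogram:
    """Run the full pipeline on a pooled collection.

    ``w`` defaults to the collection's MMAI.  Stage order is standardize →
    moving average → (interpolate) → rescale, so with interpolation every
    final curve attains exactly 100 on the integer grid.
    """
    mmai = minimum_mai(c)
    if w is None:
        w = mmai
    hooks = _standardize_collection(c)
    points = moving_average(hooks, w, mmai=mmai)
    if interpolate:
        points = interpolate_curves(points)
    points = rescale_to_collection_max(points)
    return Meristogram(
        label=c.label,
        mai=int(w),
        interpolated=interpolate,
        points=tuple(points),
        provenance={"rows": c.n_rows, "hooks": c.n_hooks},
    )


def peak_positions(m: Meristogram) -> dict[str, float]:
    """Percent-position of the maximum of each curve; ties resolve to the
    smallest (most distal) position."""
    if not m.points:
        raise ValueError("empty meristogram")
    x = m.x
    return {v: float(x[int(np.argmax(m.curve(v)))]) for v in VARIABLES}
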