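"""Validation of the triangular hook-area approximation.

The meristogram estimates hook cross-sectional area as length × base / 2.
Given a table pairing those estimates with areas digitized from hooks seen
in profile, this module regresses the estimate on the measurement by
ordinary least squares; a slope near 1, a small intercept and a high R²
indicate the triangle is an adequate proxy.  Since meristogram curves are
standardized within rows, the estimate only ever needs to be proportional
to the true area — the regression quantifies how much better than that it
actually is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .hookio import FormatError

__all__ = ["AreaRecord", "RegressionResult", "read_area_csv", "regress_estimated_on_measured"]

logger = logging.getLogger(__name__)

AREA_HEADER = (
    "species",
    "sex",
    "specimen",
    "hook",
    "position",
    "length",
    "base",
    "measured_area",
    "estimated_area",
)


@dataclass(frozen=True)
class AreaRecord:
    species: str
    sex: str
    specimen: str
    ordinal: int
    length: float
    base: float
    measured_area: float
    estimated_area: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def read_area_csv(path: str | Path, *, species: str | None = None) -> list[AreaRecord]:
    """Read the nine-column area-validation table, optionally filtered to one
    species-group label.

    A stored ``estimated_area`` deviating more than 0.5 % from
    length·base/2 triggers a warning naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if tuple(df.columns) != AREA_HEADER:
        raise FormatError(
            f"{path}: header must be exactly {','.join(AREA_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if species is not None:
        df = df[df["species"].astype(str) == species]

    records = []
    for i, row in df.iterrows():
        est = float(row["estimated_area"])
        recomputed = float(row["length"]) * float(row["base"]) / 2.0
        if recomputed > 0 and abs(est - recomputed) / recomputed > 0.005:
            logger.warning(
                "%s row %d (specimen %r, hook %d): stored estimated_area %.4g "
                "deviates >0.5%% from length*base/2 = %.4g",
                path,
                i,
                row["specimen"],
                int(row["hook"]),
                est,
                recomputed,
            )
        records.append(
            AreaRecord(
                species=str(row["species"]),
                sex=str(row["sex"]),
                specimen=str(row["specimen"]),
                ordinal=int(row["hook"]),
                length=float(row["length"]),
                base=float(row["base"]),
                measured_area=float(row["measured_area"]),
                estimated_area=est,
            )
        )
    return records


def regress_estimated_on_measured(records: list[AreaRecord]) -> RegressionResult:
    """OLS of estimated area (response) on measured area (predictor).

    For simple OLS the reported R² equals the squared Pearson correlation of
    the two variables.
    """
    if len(records) < 3:
        raise ValueError(f"regression needs at least 3 records, got {len(records)}")
    measured = [r.measured_area for r in records]
    estimated = [r.estimated_area for r in records]
    if len(set(measured)) < 2:
        raise ValueError("measured areas are constant; regression is degenerate")
    fit = stats.linregress(measured, estimated)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(records),
    )
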