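"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from meristo.core import CurvePoint
from meristo.hookio import HookCollection, HookRecord, HookRow

# Repository-root directory where users may place the published
# Echinorhynchus hook-measurement CSVs to enable the real-data checks.
DATA_DIR = Path(__file__).resolve().parent.parent / "data"

# label -> list of (filename, sex, surface) for the published study files
STUDY_FILES = {
    "E. bothniensis": [
        ("oo_63705.csv", "female", "unknown"),
        ("oo_63706.csv", "male", "unknown"),
    ],
    "E. 'bothniensis'": [("oo_63707.csv", "female", "unknown")],
    "E. brayi": [
        ("oo_63694.csv", "female", "unknown"),
        ("oo_63695.csv", "male", "unknown"),
    ],
    "E. gadi sp. A": [
        ("oo_63710.csv", "female", "unknown"),
        ("oo_63711.csv", "male", "unknown"),
    ],
    "E. gadi sp. B": [
        ("oo_63712.csv", "female", "unknown"),
        ("oo_63713.csv", "male", "unknown"),
    ],
    "E. gadi sp. I": [
        ("oo_63714.csv", "female", "unknown"),
        ("oo_63715.csv", "male", "unknown"),
    ],
    "E. salmonis": [
        ("oo_63696.csv", "female", "dorsal"),
        ("oo_63699.csv", "female", "ventral"),
        ("oo_63701.csv", "male", "dorsal"),
        ("oo_63703.csv", "male", "ventral"),
    ],
    "E. truttae Drummore": [
        ("oo_68461.csv", "female", "unknown"),
        ("oo_68463.csv", "male", "unknown"),
    ],
    "E. truttae Carron": [
        ("oo_68464.csv", "female", "unknown"),
        ("oo_68466.csv", "male", "unknown"),
    ],
}

AREA_FILE = "oo_63675.csv"


def require_study_data(*filenames: str) -> None:
    """Fail (not skip) when the published hook-measurement files are absent.

    The files are third-party research data distributed with the original
    study; they are not redistributed inside this repository.  Placing them
    under ``data/`` at the repository root turns these checks on.
    """
    missing = [f for f in filenames if not (DATA_DIR / f).exists()]
    if missing:
        pytest.fail(
            "published hook-measurement data not available: expected "
            f"{missing} under {DATA_DIR}; obtain the study's supplementary "
            "CSV files and place them there to run this real-data check",
            pytrace=False,
        )


def make_row(lengths, bases, specimen="w1", **kw) -> HookRow:
    records = tuple(
        HookRecord(ordinal=i + 1, length=float(l), base=float(b))
        for i, (l, b) in enumerate(zip(lengths, bases))
    )
    return HookRow(specimen=specimen, records=records, **kw)


def make_collection(rows, label="test") -> HookCollection:
    return HookCollection(label=label, rows=tuple(rows))


@pytest.fixture
def simple_collection() -> HookCollection:
    """Two rows of different lengths with smooth unimodal trends."""
    rng = np.random.default_rng(42)
    rows = []
    for i, n in enumerate((7, 9)):
        u = np.arange(1, n + 1) / (n + 1)
        lengths = 60 + 30 * np.exp(-((u - 0.35) ** 2) / 0.05)
        bases = 18 + 8 * np.exp(-((u - 0.6) ** 2) / 0.05)
        rows.append(make_row(lengths, bases, specimen=f"w{i + 1}"))
    return make_collection(rows)


def brute_force_moving_average(hooks, w: int) -> list[CurvePoint]:
    """Independent re-implementation of the smoothing step: explicit double
    loop over window offsets and hooks, python arithmetic only."""
    results = []
    previous_set = None
    for s in range(0, 101 - w):
        inside = [h for h in hooks if s <= h.p < s + w]
        ids = tuple(sorted(id(h) for h in inside))
        if not inside or ids == previous_set:
            if inside:
                previous_set = ids
            continue
        previous_set = ids
        k = len(inside)
        results.append(
            CurvePoint(
                x=sum(h.p for h in inside) / k,
                L=sum(h.l for h in inside) / k,
                B=sum(h.b for h in inside) / k,
                A=sum(h.a for h in inside) / k,
                R=sum(h.r for h in inside) / k,
            )
        )
    results = sorted(results, key=lambda pt: pt.x)
    unique = []
    for pt in results:
        if unique and pt.x == unique[-1].x:
            continue
        unique.append(pt)
    return unique
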