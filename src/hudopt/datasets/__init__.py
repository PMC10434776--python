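"""Packaged study tables and synthetic data generators.

Three printed tables from the AR-HUD driving-simulator study ship with
the package as verbatim CSV transcriptions:

* ``table1`` — per-sample eye-movement statistics (gaze, glance,
  reaction, NASA-TLX, paired-test p, 95% CI) for the 240 samples;
* ``table3`` — the surrogate training set: 240 (26-bit code, NASA-TLX)
  pairs;
* ``table4`` — Cooper-Harper grade-pair counts comparing the two
  optimized interfaces across 15 raters.

The tables are kept exactly as printed, including their internal
inconsistencies (a p-value above 1, inverted confidence bounds,
non-one-hot chromosome codes, grade-pair counts that disagree with the
printed category sums).  Loaders validate checksums and row counts and
flag the anomalies rather than correcting them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ..errors import CorruptedFixtureError
from .synthetic import (
    SyntheticScene,
    make_synthetic_load_dataset,
    make_synthetic_scene,
    synthetic_truth_function,
)

__all__ = [
    "LoadDataset",
    "EyeMovementTable",
    "CHGradeTable",
    "SyntheticScene",
    "load_table",
    "make_synthetic_load_dataset",
    "make_synthetic_scene",
    "synthetic_truth_function",
]

_CHECKSUMS = {
    "table1.csv": "e740f00fd8f15b7b71ddbab172ee4513705dd1505788c0460bb7d1fb68ea0ee6",
    "table3.csv": "3dbbd38dd8e351fb5e58ba6e1f12bafcb76e6b36f881ce7a096d2d82f1240acf",
    "table4.csv": "241066da2e1f41c4ea9ceb88082db1a6ac6647cdb94f8d908b2ad392ef5fc99f",
}


@dataclass(frozen=True)
class LoadDataset:
    """(chromosome code, NASA-TLX score) pairs for surrogate training."""

    codes: tuple[str, ...]
    scores: np.ndarray

    @property
    def rows(self) -> list[tuple[str, float]]:
        return list(zip(self.codes, map(float, self.scores)))

    def __len__(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"code": self.codes, "nasa_tlx": self.scores})


@dataclass(frozen=True)
class EyeMovementTable:
    """Eye-movement metrics per sample, with per-row validity flags.

    The gaze/glance columns print sub-1 values despite their ms unit
    label; they are stored as printed with ``units='as-printed'``.
    ``flagged_rows`` lists 1-based row numbers whose p-value falls
    outside [0, 1] or whose CI bounds are inverted.
    """

    frame: pd.DataFrame
    flagged_rows: tuple[int, ...]
    units: str = "as-printed"

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CHGradeTable:
    """Cooper-Harper grade-pair counts for the two-interface comparison.

    ``category_sums`` are the printed per-category totals, which are the
    authoritative counts; ``sum_mismatch`` flags categories whose listed
    grade-pair rows do not add up to the printed sum.
    """

    rows: tuple[tuple[str, str, int], ...]
    category_sums: dict[str, int] = field(default_factory=dict)
    sum_mismatch: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.category_sums.values())


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files(__package__) / "data" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise CorruptedFixtureError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), dtype={"code": str})


def load_table(name: str) -> LoadDataset | EyeMovementTable | CHGradeTable:
    """Load and validate one of the packaged study tables.

    Parameters
    ----------
    name : {'table1', 'table3', 'table4'}
    """
    if name == "table3":
        df = _read_fixture("table3.csv")
        if len(df) != 240:
            raise CorruptedFixtureError(f"table3: expected 240 rows, got {len(df)}")
        scores = df["nasa_tlx"].to_numpy(float)
        if not ((scores >= 0) & (scores <= 21)).all():
            raise CorruptedFixtureError("table3: NASA-TLX scores outside [0, 21]")
        if not all(len(c) == 26 and set(c) <= {"0", "1"} for c in df["code"]):
            raise CorruptedFixtureError("table3: malformed chromosome code")
        return LoadDataset(tuple(df["code"]), scores)
    if name == "table1":
        df = _read_fixture("table1.csv")
        if len(df) != 240:
            raise CorruptedFixtureError(f"table1: expected 240 rows, got {len(df)}")
        bad_p = (df["p_value"] < 0) | (df["p_value"] > 1)
        bad_ci = df["ci95_low"] >= df["ci95_high"]
        flagged = tuple(int(n) for n in df.loc[bad_p | bad_ci, "num"])
        return EyeMovementTable(df, flagged)
    if name == "table4":
        df = _read_fixture("table4.csv")
        sums = {r.grade_pair: int(r.n) for r in df[df["category"] == "sum"].itertuples()}
        body = df[df["category"] != "sum"]
        rows = tuple((r.category, r.grade_pair, int(r.n)) for r in body.itertuples())
        mismatch = tuple(
            cat
            for cat, printed in sums.items()
            if int(body.loc[body["category"] == cat, "n"].sum()) != printed
        )
        if sum(sums.values()) != 15:
            raise CorruptedFixtureError("table4: printed category sums must total 15")
        return CHGradeTable(rows, sums, mismatch)
    raise ValueError(f"unknown table {name!r}; expected table1, table3 or table4")
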