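"""Factorial extraction-design data: containers, validation, scaling, splits.

The packaged fixture is the 27-run 3x3x3 full factorial chamomile
microwave-assisted-extraction dataset: microwave power (400/600/800 W),
extraction time (20/30/40 min) and solid-to-solvent ratio 1:X encoded as the
solvent parts X (40/60/80), with the measured total phenolic content (TPC,
mg gallic-acid equivalents per g) as the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_COLUMNS",
    "RESPONSE_COLUMN",
    "FIXTURE_ID",
    "DesignPoint",
    "ExtractionRecord",
    "Dataset",
    "ScalingSpec",
    "DataValidationError",
    "DegenerateScaleError",
    "load_design_table",
    "fit_scaler",
    "split_train_test",
]

FACTOR_COLUMNS = ("power_W", "time_min", "solvent_parts")
RESPONSE_COLUMN = "tpc"

#: identifier accepted by :func:`load_design_table` for the packaged dataset
FIXTURE_ID = "chamomile-mae"

_FIXTURE_RESOURCE = "factorial_design.csv"


class DataValidationError(ValueError):
    """A design table failed validation; the message names the offender."""


class DegenerateScaleError(ValueError):
    """A column is constant and cannot be mapped onto a proper interval."""


@dataclass(frozen=True)
class DesignPoint:
    """One setting of the three extraction factors, in raw units."""

    power_W: float
    time_min: float
    solvent_parts: float

    def __post_init__(self) -> None:
        for name in FACTOR_COLUMNS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise DataValidationError(
                    f"DesignPoint.{name} must be finite and > 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.power_W, self.time_min, self.solvent_parts], dtype=float
        )


@dataclass(frozen=True)
class ExtractionRecord:
    """A design point together with its observed TPC yield (mg/g)."""

    point: DesignPoint
    tpc: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tpc) and self.tpc > 0):
            raise DataValidationError(
                f"tpc must be finite and > 0, got {self.tpc!r}"
            )


@dataclass(frozen=True)
class Dataset:
    """An ordered, duplicate-free collection of extraction records."""

    records: tuple[ExtractionRecord, ...]
    name: str = "dataset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[tuple[float, float, float], int] = {}
        for i, rec in enumerate(self.records):
            key = (rec.point.power_W, rec.point.time_min, rec.point.solvent_parts)
            if key in seen:
                raise DataValidationError(
                    f"duplicate design point {key} at rows "
                    f"{seen[key]} and {i} of {self.name!r}"
                )
            seen[key] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def X(self) -> np.ndarray:
        """Factor matrix, shape (n, 3), raw units."""
        return np.array([r.point.as_array() for r in self.records])

    @property
    def y(self) -> np.ndarray:
        """Response vector (TPC, mg/g), shape (n,)."""
        return np.array([r.tpc for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.X, self.y]),
            columns=[*FACTOR_COLUMNS, RESPONSE_COLUMN],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _dataset_from_frame(df: pd.DataFrame, name: str) -> Dataset:
    missing = [c for c in (*FACTOR_COLUMNS, RESPONSE_COLUMN) if c not in df.columns]
    if missing:
        raise DataValidationError(f"{name!r}: missing column(s) {missing}")
    if len(df) == 0:
        raise DataValidationError(f"{name!r}: table is empty")
    records = []
    for i, row in df.iterrows():
        for col in (*FACTOR_COLUMNS, RESPONSE_COLUMN):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise DataValidationError(
                    f"{name!r}: non-numeric value {row[col]!r} "
                    f"in column {col!r}, row {i}"
                ) from None
        point = DesignPoint(
            power_W=float(row["power_W"]),
            time_min=float(row["time_min"]),
            solvent_parts=float(row["solvent_parts"]),
        )
        records.append(ExtractionRecord(point=point, tpc=float(row[RESPONSE_COLUMN])))
    return Dataset(records=tuple(records), name=name)


def load_design_table(source: str | Path = FIXTURE_ID) -> Dataset:
    """Load a factorial design table from a CSV path or the packaged fixture.

    ``source=FIXTURE_ID`` (the default) loads the packaged 27-run chamomile
    dataset. A CSV must carry the header
    ``power_W,time_min,solvent_parts,tpc``.
    """
    if source == FIXTURE_ID:
        ref = resources.files("chamopt.data").joinpath(_FIXTURE_RESOURCE)
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
        return _dataset_from_frame(df, name=FIXTURE_ID)
    path = Path(source)
    if not path.exists():
        raise DataValidationError(f"no such design table: {path}")
    return _dataset_from_frame(pd.read_csv(path), name=str(path))


@dataclass(frozen=True)
class ScalingSpec:
    """Affine per-column min-max map onto a target interval (default [-1, 1]).

    Columns are the three factors followed by the response; the forward map
    sends each raw column's [min, max] onto [lo, hi] exactly, and ``inverse``
    undoes it.
    """

    mins: np.ndarray  # length 4: factors then response
    maxs: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        if not self.hi > self.lo:
            raise DegenerateScaleError("target interval must have hi > lo")
        if np.any(maxs <= mins):
            bad = int(np.argmax(maxs <= mins))
            raise DegenerateScaleError(
                f"column {bad} is constant (min == max == {mins[bad]})"
            )

    def _fwd(self, v: np.ndarray, j: slice | int) -> np.ndarray:
        lo, hi = self.lo, self.hi
        return lo + (np.asarray(v, float) - self.mins[j]) * (hi - lo) / (
            self.maxs[j] - self.mins[j]
        )

    def _inv(self, v: np.ndarray, j: slice | int) -> np.ndarray:
        lo, hi = self.lo, self.hi
        return self.mins[j] + (np.asarray(v, float) - lo) * (
            self.maxs[j] - self.mins[j]
        ) / (hi - lo)

    def forward_X(self, X: np.ndarray) -> np.ndarray:
        return self._fwd(X, slice(0, 3))

    def inverse_X(self, Xs: np.ndarray) -> np.ndarray:
        return self._inv(Xs, slice(0, 3))

    def forward_y(self, y: np.ndarray) -> np.ndarray:
        return self._fwd(y, 3)

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        return self._inv(ys, 3)


def fit_scaler(dataset: Dataset, target: tuple[float, float] = (-1.0, 1.0)) -> ScalingSpec:
    """Fit the min-max scaling of the factors and response onto ``target``."""
    X, y = dataset.X, dataset.y
    mins = np.append(X.min(axis=0), y.min())
    maxs = np.append(X.max(axis=0), y.max())
    return ScalingSpec(mins=mins, maxs=maxs, lo=float(target[0]), hi=float(target[1]))


def split_train_test(
    dataset: Dataset | int, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test partition of the record indices.

    The train size is ``round(train_fraction * n)`` with ties rounded half away
    from zero; indices are drawn without replacement from a seeded uniform
    permutation, so identical ``(n, train_fraction, seed)`` give identical
    partitions. Both returned index arrays are sorted.
    """
    n = dataset if isinstance(dataset, int) else len(dataset)
    if not 0.0 < train_fraction < 1.0:
        raise DataValidationError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    n_train = int(math.floor(train_fraction * n + 0.5))
    if n_train < 1 or n_train >= n:
        raise DataValidationError(
            f"train_fraction {train_fraction} leaves an empty partition for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
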