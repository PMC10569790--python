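"""Reading and writing the pipeline's delimited interchange formats.

The unit of input data is a long-format table of ROI time series with
columns ``animal, group, roi, period, t, value`` — one row per sample.
Feature matrices and result tables are plain CSV with a one-line header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix
from .synthdata import CohortDataset

__all__ = [
    "REQUIRED_COLUMNS",
    "TimeSeriesData",
    "write_cohort",
    "read_time_series",
    "ValidationReport",
    "validate_input",
    "write_feature_matrix",
    "read_feature_matrix",
]

REQUIRED_COLUMNS = ("animal", "group", "roi", "period", "t", "value")


@dataclass
class TimeSeriesData:
    """ROI time series keyed by (animal, roi, period), plus group labels."""

    series: dict[tuple[str, str, str], np.ndarray]
    groups: dict[str, str]
    behavior: dict[str, float] = field(default_factory=dict)

    @property
    def animals(self) -> list[str]:
        return sorted(self.groups)

    @property
    def rois(self) -> list[str]:
        return sorted({k[1] for k in self.series})

    @property
    def periods(self) -> list[str]:
        return sorted({k[2] for k in self.series})

    def roi_period_series(self, roi: str, period: str) -> dict[str, np.ndarray]:
        return {
            a: self.series[(a, roi, period)]
            for a in self.animals
            if (a, roi, period) in self.series
        }


def write_cohort(cohort: CohortDataset | TimeSeriesData, path: str | Path) -> None:
    """Serialize a cohort to the long-format delimited table."""
    rows = []
    for (animal, roi, period), values in sorted(cohort.series.items()):
        group = cohort.groups[animal]
        rows.append(
            pd.DataFrame(
                {
                    "animal": animal,
                    "group": group,
                    "roi": roi,
                    "period": period,
                    "t": np.arange(len(values)),
                    "value": values,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_time_series(path: str | Path) -> TimeSeriesData:
    """Read the long-format table back into keyed arrays."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    series: dict[tuple[str, str, str], np.ndarray] = {}
    groups: dict[str, str] = {}
    for (animal, group, roi, period), sub in df.groupby(
        ["animal", "group", "roi", "period"], sort=True
    ):
        series[(str(animal), str(roi), str(period))] = (
            sub.sort_values("t")["value"].to_numpy(dtype=float)
        )
        groups[str(animal)] = str(group)
    return TimeSeriesData(series, groups)


@dataclass
class ValidationReport:
    """Structured outcome of input validation; empty issue list means valid."""

    path: str
    n_rows: int
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        status = "OK" if self.ok else f"{len(self.issues)} issue(s)"
        body = "\n".join(f"  - {i}" for i in self.issues)
        return f"{self.path}: {self.n_rows} rows, {status}" + ("\n" + body if body else "")


def validate_input(
    path: str | Path,
    expected_samples: int = 900,
    allowed_groups: tuple[str, ...] | None = None,
) -> ValidationReport:
    """Check schema, per-key sample counts, labels and finiteness.

    Never mutates the data; returns a report listing every problem found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    issues: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        issues.append(f"missing columns: {missing}")
        return ValidationReport(str(path), len(df), issues)

    bad = df.index[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
    for i in bad[:20]:
        issues.append(f"non-finite value at line {i + 2}")  # +2: header + 0-base
    if len(bad) > 20:
        issues.append(f"... and {len(bad) - 20} more non-finite values")

    if allowed_groups is not None:
        unknown = sorted(set(df["group"].astype(str)) - set(allowed_groups))
        for g in unknown:
            issues.append(f"unknown group label: {g!r}")

    grp = df.groupby(["animal", "roi", "period"], sort=True).size()
    for key, n in grp.items():
        if n != expected_samples:
            issues.append(
                f"animal={key[0]} roi={key[1]} period={key[2]}: "
                f"{n} samples (expected {expected_samples})"
            )

    per_animal = df.groupby("animal")["group"].nunique()
    for a in per_animal.index[per_animal > 1]:
        issues.append(f"animal {a} has multiple group labels")
    return ValidationReport(str(path), len(df), issues)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """CSV with the animal index, group column, then one column per feature."""
    out = matrix.data.copy()
    out.insert(0, "group", matrix.groups)
    out.index.name = "animal"
    out.to_csv(path)


def read_feature_matrix(path: str | Path, roi: str = "", period: str = "") -> FeatureMatrix:
    df = pd.read_csv(path, index_col="animal", float_precision="round_trip")
    groups = df.pop("group")
    return FeatureMatrix(roi=roi, period=period, data=df, groups=groups)
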