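"""Per-ROI feature matrices: assembly, filtering, deltas and normalization.

The analysis unit is an animals x features matrix for one ROI and one scan
period.  Poorly behaved features (non-finite anywhere, or constant across
animals) are removed with a mask shared across all ROIs entering a
comparison; the classification input is the post-minus-baseline delta
matrix, normalized per feature with an outlier-robust sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureCatalog, default_catalog, extract_feature_vector

__all__ = [
    "FeatureMatrix",
    "DeltaFeatureMatrix",
    "build_feature_matrix",
    "well_behaved_mask",
    "delta_features",
    "robust_sigmoid_normalize",
    "normalize_matrix",
]


@dataclass
class FeatureMatrix:
    """Animals x features values for one ROI and one period."""

    roi: str
    period: str
    data: pd.DataFrame  # index: animal id, columns: feature ids
    groups: pd.Series  # index: animal id, values: group label

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            raise ValueError("every animal needs a group label")


@dataclass
class DeltaFeatureMatrix:
    """Post-minus-baseline feature changes for one ROI."""

    roi: str
    data: pd.DataFrame
    groups: pd.Series


def build_feature_matrix(
    series: Mapping[str, Sequence[float]],
    roi: str,
    period: str,
    groups: Mapping[str, str],
    catalog: FeatureCatalog | None = None,
) -> FeatureMatrix:
    """Extract the full catalogue for each animal's series in one ROI/period."""
    if catalog is None:
        catalog = default_catalog()
    rows = {}
    for animal, ts in series.items():
        fv = extract_feature_vector(ts, catalog)
        rows[animal] = fv.values
    data = pd.DataFrame.from_dict(rows, orient="index", columns=catalog.feature_ids)
    data = data.sort_index()
    grp = pd.Series({a: groups[a] for a in data.index}, name="group")
    return FeatureMatrix(roi=roi, period=period, data=data, groups=grp)


def well_behaved_mask(matrices: Iterable[FeatureMatrix | DeltaFeatureMatrix]) -> pd.Index:
    """Feature ids finite for every animal/period/ROI and non-constant.

    The mask is intended to be shared across every matrix entering a joint
    analysis, mirroring the removal of features that return NaN, infinities
    or errors on any recording.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    keep = None
    for m in matrices:
        finite = m.data.notna().all(axis=0) & np.isfinite(m.data).all(axis=0)
        varying = m.data.nunique(dropna=False) > 1
        ok = finite & varying
        keep = ok if keep is None else (keep & ok)
    retained = keep[keep].index
    if retained.empty:
        raise ValueError("no well-behaved features retained")
    return retained


def delta_features(post: FeatureMatrix, baseline: FeatureMatrix) -> DeltaFeatureMatrix:
    """Elementwise post - baseline with strict row/column alignment."""
    if post.roi != baseline.roi:
        raise ValueError("matrices belong to different ROIs")
    if set(post.data.index) != set(baseline.data.index):
        raise ValueError("animal sets differ between periods")
    if list(post.data.columns) != list(baseline.data.columns):
        raise ValueError("feature sets differ between periods")
    base = baseline.data.loc[post.data.index]
    return DeltaFeatureMatrix(
        roi=post.roi, data=post.data - base, groups=post.groups.copy()
    )


def robust_sigmoid_normalize(column: Sequence[float]) -> np.ndarray:
    """Outlier-robust sigmoidal transform of one feature column.

    ``x -> 1 / (1 + exp(-(x - median) / (1.35 * IQR)))``: centred on the
    median, scaled by the interquartile range so extreme values saturate
    instead of dominating.  Raises on zero IQR.
    """
    x = np.asarray(column, dtype=float)
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("zero IQR: column cannot be sigmoid-normalized")
    return 1.0 / (1.0 + np.exp(-(x - med) / (1.35 * iqr)))


def normalize_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Apply the robust sigmoid per feature column; drop zero-IQR columns.

    Returns the normalized matrix and the list of dropped feature ids.
    """
    out = {}
    dropped: list[str] = []
    for col in data.columns:
        try:
            out[col] = robust_sigmoid_normalize(data[col].to_numpy())
        except ValueError:
            dropped.append(col)
    if not out:
        raise ValueError("all columns dropped during normalization")
    norm = pd.DataFrame(out, index=data.index)
    return norm, dropped
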