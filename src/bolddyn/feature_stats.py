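"""Feature-level inference for one ROI contrast.

Each feature's discriminability between two groups is scored with the
signed Mann-Whitney rank-sum statistic — here the normal-approximation z,
positive when the stimulation group's values are larger — with BH-FDR
across features.  The top discriminative features are organized by
hierarchical average-linkage clustering under the absolute-Spearman
distance 1 - |rho|, and feature-score vectors of two regions are compared
with a correlated group-label shuffle test that preserves the within-animal
dependence across regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import statcore
from .statcore import PermutationSpec

__all__ = [
    "ranksum_z_scores",
    "score_features",
    "FeatureSimilarity",
    "cluster_top_features",
    "cross_region_score_correlation",
]


def ranksum_z_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise signed rank-sum z between the two label groups.

    ``X`` is animals x features; ``y`` is binary with 1 the stimulation
    group.  The z is the tie-corrected normal approximation of the
    Mann-Whitney U counting pairs where a group-0 value is below a group-1
    value, so positive z means the stimulation group is larger.  Columns
    with zero rank variance come back NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    n2 = int(y.sum())
    n1 = n - n2
    ranks = stats.rankdata(X, axis=0)
    r2 = ranks[y == 1].sum(axis=0)
    u = r2 - n2 * (n2 + 1) / 2.0

    tie_term = np.zeros(X.shape[1])
    srt = np.sort(X, axis=0)
    has_ties = np.any(srt[1:] == srt[:-1], axis=0)
    for j in np.nonzero(has_ties)[0]:
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    z[var <= 0] = np.nan
    return z


def score_features(
    delta_group1: pd.DataFrame, delta_group2: pd.DataFrame
) -> pd.DataFrame:
    """Signed feature scores comparing two groups' delta features.

    ``delta_group1`` holds the control rows and ``delta_group2`` the
    stimulation rows (same feature columns).  Returns a table indexed by
    feature id with columns ``score`` (signed z), ``p`` (two-sided normal)
    and ``p_fdr``; degenerate columns carry NaN and are excluded from the
    FDR family.
    """
    if list(delta_group1.columns) != list(delta_group2.columns):
        raise ValueError("feature sets differ between groups")
    if len(delta_group1) < 3 or len(delta_group2) < 3:
        raise ValueError("need at least 3 animals per group")
    X = np.vstack([delta_group1.to_numpy(float), delta_group2.to_numpy(float)])
    y = np.r_[np.zeros(len(delta_group1), int), np.ones(len(delta_group2), int)]
    z = ranksum_z_scores(X, y)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"score": z, "p": p}, index=delta_group1.columns)
    valid = np.isfinite(z)
    q = np.full(z.shape, np.nan)
    if valid.any():
        q[valid] = statcore.bh_fdr(p[valid])
    table["p_fdr"] = q
    return table


@dataclass
class FeatureSimilarity:
    """Pairwise feature similarity structure for a feature subset."""

    feature_ids: list[str]
    distance: pd.DataFrame  # 1 - |spearman rho|, symmetric, zero diagonal
    linkage: np.ndarray  # scipy average-linkage merge tree
    leaf_order: list[str]
    excluded: list[str]

    def flat_clusters(self, cut: float) -> pd.Series:
        """Flat cluster labels from cutting the tree at a distance."""
        labels = hierarchy.fcluster(self.linkage, t=cut, criterion="distance")
        return pd.Series(labels, index=self.feature_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick serialization of the merge tree (leaf names, node heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.feature_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster_top_features(values: pd.DataFrame) -> FeatureSimilarity:
    """Cluster features by behavior across animals.

    ``values`` is animals x features (e.g. the delta features of the top-100
    scoring set).  Distance is the absolute Spearman correlation distance
    ``1 - |rho|``; the tree is average linkage.  Constant columns are
    excluded and reported.
    """
    if values.shape[1] < 2 or values.shape[0] < 4:
        raise ValueError("need >= 2 features and >= 4 animals")
    const = values.columns[values.nunique() <= 1].tolist()
    vals = values.drop(columns=const)
    if vals.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")
    rho = stats.spearmanr(vals.to_numpy(float)).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-feature case
        r = float(stats.spearmanr(vals.iloc[:, 0], vals.iloc[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    d = np.clip(1.0 - np.abs(rho), 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    ids = vals.columns.tolist()
    order = [ids[i] for i in hierarchy.leaves_list(link)]
    dist = pd.DataFrame(d, index=ids, columns=ids)
    return FeatureSimilarity(ids, dist, link, order, const)


def cross_region_score_correlation(
    data_r1: pd.DataFrame,
    data_r2: pd.DataFrame,
    labels: Sequence,
    perm_spec: PermutationSpec,
    alternative: str = "greater",
) -> tuple[float, float, np.ndarray]:
    """Are feature-score changes similar in two regions?

    Computes the Spearman correlation between the two regions' feature-score
    vectors, then builds the null with correlated group-label shuffles: each
    permutation reassigns animal labels once and applies the same assignment
    to both regions before recomputing both score vectors.  The default
    one-sided p (add-one rule) tests for positive correlation; pass
    ``alternative="two-sided"`` for a magnitude test.
    """
    if not data_r1.index.equals(data_r2.index):
        raise ValueError("the two regions must cover the same animals")
    cols = [c for c in data_r1.columns if c in set(data_r2.columns)]
    X1 = data_r1[cols].to_numpy(float)
    X2 = data_r2[cols].to_numpy(float)
    y = np.asarray(labels)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError("need exactly two classes")
    yb = (y == uniq[1]).astype(int)

    def _rho(y_now: np.ndarray) -> float:
        z1 = ranksum_z_scores(X1, y_now)
        z2 = ranksum_z_scores(X2, y_now)
        ok = np.isfinite(z1) & np.isfinite(z2)
        if ok.sum() < 3:
            return float("nan")
        return float(stats.spearmanr(z1[ok], z2[ok]).statistic)

    observed = _rho(yb)
    rng = np.random.default_rng(perm_spec.seed)
    null = np.array(
        [_rho(rng.permutation(yb)) for _ in range(perm_spec.n_permutations)]
    )
    if alternative == "greater":
        p = statcore.perm_pvalue(observed, null)
    elif alternative == "two-sided":
        p = statcore.perm_pvalue(abs(observed), np.abs(null))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return observed, p, null
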