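"""Windowed functional connectivity (FC) and its neuromodulation-induced change.

FC between a seed region and a target is the Pearson correlation of their
BOLD series, computed per minute (non-overlapping 60-sample windows at 1 s
sampling, so a 900-sample period yields 15 values).  Per-animal period means
give the baseline and post-injection FC and their difference, dFC = post -
baseline.  Baseline FC is tested against zero with one-sample Wilcoxon tests
(FDR across region pairs); group differences in dFC use a permutation test
on the difference of group means; behavior is linked to dFC with a Pearson
correlation of the per-animal rotation asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import statcore
from .statcore import PermutationSpec

__all__ = [
    "fc_per_minute",
    "FcRecord",
    "fc_record",
    "baseline_fc_test",
    "group_delta_fc_test",
    "behavior_fc_correlation",
]


def fc_per_minute(
    ts_a: Sequence[float], ts_b: Sequence[float], window: int = 60
) -> np.ndarray:
    """Pearson r per non-overlapping window, in temporal order.

    A trailing remainder shorter than one window is dropped; a window in
    which either series is constant yields NaN (excluded from period means).
    """
    a = np.asarray(ts_a, dtype=float)
    b = np.asarray(ts_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series lengths differ")
    n_win = a.size // window
    if n_win == 0:
        raise ValueError("series shorter than one window")
    out = np.empty(n_win)
    for w in range(n_win):
        xa = a[w * window:(w + 1) * window]
        xb = b[w * window:(w + 1) * window]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            out[w] = np.nan
            continue
        out[w] = np.corrcoef(xa, xb)[0, 1]
    return out


@dataclass(frozen=True)
class FcRecord:
    """Per-animal FC between one region pair across both periods."""

    animal: str
    group: str
    seed: str
    target: str
    baseline_minutes: np.ndarray
    post_minutes: np.ndarray

    @property
    def baseline_mean(self) -> float:
        return float(np.nanmean(self.baseline_minutes))

    @property
    def post_mean(self) -> float:
        return float(np.nanmean(self.post_minutes))

    @property
    def delta_fc(self) -> float:
        return self.post_mean - self.baseline_mean


def fc_record(
    animal: str,
    group: str,
    seed: str,
    target: str,
    baseline_a: Sequence[float],
    baseline_b: Sequence[float],
    post_a: Sequence[float],
    post_b: Sequence[float],
    window: int = 60,
) -> FcRecord:
    """Build the per-minute FC record for one animal and region pair."""
    return FcRecord(
        animal, group, seed, target,
        fc_per_minute(baseline_a, baseline_b, window),
        fc_per_minute(post_a, post_b, window),
    )


def baseline_fc_test(
    baseline_means: pd.DataFrame, fdr_level: float = 0.01
) -> pd.DataFrame:
    """One-sample Wilcoxon test of baseline FC against zero, per region pair.

    ``baseline_means`` is animals x region-pairs of per-animal baseline FC
    (all groups pooled).  Returns a table per pair with the median FC, the
    two-sided p, the BH-FDR adjusted p, and the significance call at
    ``fdr_level``.
    """
    if len(baseline_means) < 6:
        raise ValueError("need at least 6 animals")
    rows = {}
    for pair in baseline_means.columns:
        vals = baseline_means[pair].dropna().to_numpy()
        rows[pair] = {
            "median_fc": float(np.median(vals)),
            "p": statcore.wilcoxon_signed_rank(vals),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["p_fdr"] = statcore.bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_level
    return table


def group_delta_fc_test(
    delta_fc: pd.DataFrame,
    groups: pd.Series,
    contrasts: Sequence[tuple[str, str]],
    perm_spec: PermutationSpec,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of group differences in dFC, FDR over pairs x contrasts.

    ``delta_fc`` is animals x region-pairs; ``groups`` maps animal to group.
    For each contrast ``(g_a, g_b)`` and pair, the statistic is
    ``mean(dFC | g_b) - mean(dFC | g_a)``; the null shuffles group labels
    within the two groups involved; the p is two-sided with the add-one rule.
    """
    if not delta_fc.index.equals(groups.index):
        groups = groups.reindex(delta_fc.index)
    records = []
    rng = np.random.default_rng(perm_spec.seed)
    for g_a, g_b in contrasts:
        sel = groups.isin([g_a, g_b])
        if (groups == g_a).sum() < 3 or (groups == g_b).sum() < 3:
            raise ValueError(f"need >= 3 animals per group in contrast {g_a} vs {g_b}")
        sub = delta_fc.loc[sel]
        lab = (groups[sel] == g_b).to_numpy()
        X = sub.to_numpy(float)
        obs = X[lab].mean(axis=0) - X[~lab].mean(axis=0)
        null = np.empty((perm_spec.n_permutations, X.shape[1]))
        for b in range(perm_spec.n_permutations):
            lb = rng.permutation(lab)
            null[b] = X[lb].mean(axis=0) - X[~lb].mean(axis=0)
        for j, pair in enumerate(sub.columns):
            p = (1 + np.sum(np.abs(null[:, j]) >= abs(obs[j]))) / (
                1 + perm_spec.n_permutations
            )
            records.append(
                {"contrast": f"{g_a}-vs-{g_b}", "pair": pair,
                 "delta_diff": float(obs[j]), "p": float(p)}
            )
    table = pd.DataFrame.from_records(records)
    table["p_fdr"] = statcore.bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_fdr"] < fdr_level
    return table


def behavior_fc_correlation(
    behavior: Mapping[str, float], delta_fc: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation between rotation asymmetry and dFC of one pair.

    ``behavior`` maps animal to contraversive-minus-ipsiversive rotation
    count; ``delta_fc`` maps animal to the pair's dFC.  Returns (r, p) over
    the shared animals (at least 5 required).
    """
    shared = sorted(set(behavior) & set(delta_fc))
    if len(shared) < 5:
        raise ValueError("need at least 5 shared animals")
    b = [behavior[a] for a in shared]
    d = [delta_fc[a] for a in shared]
    return statcore.pearson_r(d, b)
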