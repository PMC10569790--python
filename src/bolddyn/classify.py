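"""Region-level classification of neuromodulated vs control animals.

For each brain region, the post-minus-baseline feature changes of the two
groups are fed to a linear support vector machine with inverse-probability
class reweighting.  Performance is the balanced classification accuracy
(BCA, the arithmetic mean of sensitivity and specificity, in percent) from
stratified ten-fold cross-validation, averaged over repeated random
partitions.  Significance comes from a group-label permutation test on the
same statistic, corrected across regions by Benjamini-Hochberg FDR.

The BCA convention: held-out predictions are pooled across the ten folds of
one repeat before computing sensitivity/specificity (robust to folds that
hold a single class member, which the 10 vs 13/15 group sizes force), and
the per-repeat BCAs are then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import statcore
from .statcore import MwuResult, PermutationSpec

__all__ = [
    "balanced_accuracy",
    "repeated_cv_bca",
    "region_permutation_test",
    "pca_overfit_check",
    "compare_bca_sets",
    "hierarchy_correlation",
    "classify_regions",
    "RegionClassifier",
    "RegionClassificationResult",
]


def balanced_accuracy(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> float:
    """100 * (sensitivity + specificity) / 2; requires both classes in truth."""
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("true labels must contain exactly two classes")
    rates = [np.mean(yhat[y == c] == c) for c in classes]
    return float(100.0 * np.mean(rates))


def _encode_labels(labels: Sequence) -> np.ndarray:
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    return (lab == classes[1]).astype(int)


def _cv_bca_once(
    X: np.ndarray, y: np.ndarray, n_folds: int, rep_seed: int, C: float
) -> float:
    """One stratified k-fold pass: pooled held-out predictions -> BCA."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rep_seed + 1_000_003 * attempt)
        preds = np.empty_like(y)
        ok = True
        for tr, te in skf.split(X, y):
            if np.unique(y[tr]).size < 2:
                ok = False
                break
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            clf.fit(X[tr], y[tr])
            preds[te] = clf.predict(X[te])
        if ok:
            return balanced_accuracy(y, preds)
    raise RuntimeError("could not draw a partition with two-class training folds")


def repeated_cv_bca(
    X,
    labels: Sequence,
    n_folds: int = 10,
    n_repeats: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """Per-repeat balanced accuracies of the linear SVM under repeated CV.

    Each repeat draws a fresh stratified partition; the result is the vector
    of per-repeat pooled BCAs (mean it for the summary statistic).
    Deterministic for a given seed.
    """
    X = np.ascontiguousarray(pd.DataFrame(X).to_numpy(dtype=float))
    y = _encode_labels(labels)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least two animals per class")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31 - 1)
    return np.array(
        [_cv_bca_once(X, y, n_folds, int(s), C) for s in rep_seeds]
    )


@dataclass
class RegionClassificationResult:
    """Classification outcome for one ROI and one group contrast."""

    roi: str
    contrast: str
    bca_repeats: np.ndarray
    null_bcas: np.ndarray | None = None
    p_perm: float | None = None
    p_fdr: float | None = None
    pca_dims: int | None = None
    pca_bca: float | None = None
    pca_reached: bool | None = None

    @property
    def bca_mean(self) -> float:
        return float(np.mean(self.bca_repeats))

    def summary(self) -> str:
        lines = [
            f"Region classification: {self.roi} [{self.contrast}]",
            f"  balanced accuracy : {self.bca_mean:6.1f} %"
            f"  (over {self.bca_repeats.size} CV repeats)",
        ]
        if self.p_perm is not None:
            lines.append(
                f"  permutation p     : {self.p_perm:.4g}"
                f"  ({self.null_bcas.size} label shuffles)"
            )
        if self.p_fdr is not None:
            lines.append(f"  FDR-corrected p   : {self.p_fdr:.4g}")
        if self.pca_dims is not None:
            lines.append(
                f"  PCA check         : {self.pca_bca:.1f} % with"
                f" {self.pca_dims} components"
            )
        return "\n".join(lines)


def region_permutation_test(
    X,
    labels: Sequence,
    perm_spec: PermutationSpec,
    n_folds: int = 10,
    n_repeats: int = 50,
    C: float = 1.0,
    roi: str = "",
    contrast: str = "",
) -> RegionClassificationResult:
    """Permutation significance of the mean repeated-CV BCA.

    Group labels are permuted (class sizes preserved); every permutation
    reruns the identical CV procedure with the same internal seed as the
    observed statistic (paired nulls).  The p-value uses the add-one rule.
    """
    Xc = np.ascontiguousarray(pd.DataFrame(X).to_numpy(dtype=float))
    y = _encode_labels(labels)
    ss = np.random.SeedSequence(perm_spec.seed)
    cv_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    rng = np.random.default_rng(ss.spawn(1)[0])

    # input is validated once here; skip per-fit finiteness checks in the loop
    if not np.all(np.isfinite(Xc)):
        raise ValueError("X contains non-finite values")
    with sklearn.config_context(assume_finite=True):
        observed = repeated_cv_bca(Xc, y, n_folds, n_repeats, seed=cv_seed, C=C)
        null = np.empty(perm_spec.n_permutations)
        for b in range(perm_spec.n_permutations):
            yb = rng.permutation(y)
            null[b] = repeated_cv_bca(
                Xc, yb, n_folds, n_repeats, seed=cv_seed, C=C
            ).mean()
    p = statcore.perm_pvalue(float(observed.mean()), null)
    return RegionClassificationResult(
        roi=roi, contrast=contrast, bca_repeats=observed, null_bcas=null, p_perm=p
    )


def pca_overfit_check(
    X, labels: Sequence, seed: int = 0, n_folds: int = 10, C: float = 1.0
) -> tuple[int, float, bool]:
    """Overfitting control: classify in a low-dimensional PCA space.

    Finds the smallest number of principal components whose training-fold
    in-sample balanced accuracy reaches 100% (averaged over the folds of one
    stratified partition), then reports the held-out BCA using that many
    components (PCA refit inside each training fold).  Returns
    ``(k, held_out_bca, reached)``; ``reached`` is False when 100% in-sample
    accuracy was never attained up to the sample-size cap.
    """
    Xc = np.ascontiguousarray(pd.DataFrame(X).to_numpy(dtype=float))
    y = _encode_labels(labels)
    n = Xc.shape[0]
    cap = min(n - 1, Xc.shape[1])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xc, y))

    chosen, reached = cap, False
    for k in range(1, cap + 1):
        accs = []
        for tr, _ in folds:
            if np.unique(y[tr]).size < 2:
                continue
            kk = min(k, len(tr) - 1)
            Z = PCA(n_components=kk, random_state=0).fit(Xc[tr])
            clf = SVC(kernel="linear", C=C, class_weight="balanced")
            Xt = Z.transform(Xc[tr])
            clf.fit(Xt, y[tr])
            accs.append(balanced_accuracy(y[tr], clf.predict(Xt)))
        if accs and np.mean(accs) >= 100.0 - 1e-9:
            chosen, reached = k, True
            break

    preds = np.empty_like(y)
    for tr, te in folds:
        kk = min(chosen, len(tr) - 1)
        Z = PCA(n_components=kk, random_state=0).fit(Xc[tr])
        clf = SVC(kernel="linear", C=C, class_weight="balanced")
        clf.fit(Z.transform(Xc[tr]), y[tr])
        preds[te] = clf.predict(Z.transform(Xc[te]))
    return chosen, balanced_accuracy(y, preds), reached


def compare_bca_sets(bcas_a: Sequence[float], bcas_b: Sequence[float]) -> MwuResult:
    """Two-tailed Mann-Whitney comparison of two sets of region BCAs.

    With the first argument the higher-scoring set, U counts pairs where a
    first-set value falls below a second-set value, so complete separation
    gives U = 0.
    """
    return statcore.mann_whitney(bcas_a, bcas_b)


def hierarchy_correlation(
    bcas_by_roi: Mapping[str, float],
    hierarchy_rank: Mapping[str, int],
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between regional BCA and cortical hierarchy rank."""
    shared = sorted(set(bcas_by_roi) & set(hierarchy_rank))
    if len(shared) < 5:
        raise ValueError("need at least 5 shared ROIs")
    bca = [bcas_by_roi[r] for r in shared]
    rank = [hierarchy_rank[r] for r in shared]
    return statcore.spearman_test(bca, rank, seed=seed)


class RegionClassifier:
    """Model object: delta features + binary group labels for one ROI.

    ``fit()`` runs the repeated-CV SVM, optionally with the permutation test
    and the PCA overfitting check, and returns a
    :class:`RegionClassificationResult`.
    """

    def __init__(
        self,
        X,
        labels: Sequence,
        roi: str = "",
        contrast: str = "",
        n_folds: int = 10,
        n_repeats: int = 50,
        C: float = 1.0,
    ) -> None:
        self.X = pd.DataFrame(X)
        self.labels = np.asarray(labels)
        self.roi = roi
        self.contrast = contrast
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.C = C

    def fit(
        self,
        perm_spec: PermutationSpec | None = None,
        pca_check: bool = False,
        seed: int = 0,
    ) -> RegionClassificationResult:
        if perm_spec is not None:
            res = region_permutation_test(
                self.X, self.labels, perm_spec, self.n_folds, self.n_repeats,
                self.C, roi=self.roi, contrast=self.contrast,
            )
        else:
            reps = repeated_cv_bca(
                self.X, self.labels, self.n_folds, self.n_repeats, seed, self.C
            )
            res = RegionClassificationResult(self.roi, self.contrast, reps)
        if pca_check:
            k, bca, reached = pca_overfit_check(self.X, self.labels, seed,
                                                self.n_folds, self.C)
            res.pca_dims, res.pca_bca, res.pca_reached = k, bca, reached
        return res


def classify_regions(
    delta_by_roi: Mapping[str, tuple[pd.DataFrame, Sequence]],
    perm_spec: PermutationSpec,
    n_folds: int = 10,
    n_repeats: int = 50,
    C: float = 1.0,
    contrast: str = "",
    fdr_level: float = 0.05,
) -> dict[str, RegionClassificationResult]:
    """Permutation-test every ROI and FDR-correct across the ROI set."""
    results: dict[str, RegionClassificationResult] = {}
    for i, (roi, (X, labels)) in enumerate(delta_by_roi.items()):
        spec = PermutationSpec(perm_spec.n_permutations, perm_spec.seed + i)
        results[roi] = region_permutation_test(
            X, labels, spec, n_folds, n_repeats, C, roi=roi, contrast=contrast
        )
    rois = list(results)
    adj = statcore.bh_fdr([results[r].p_perm for r in rois])
    for r, q in zip(rois, adj):
        results[r].p_fdr = float(q)
    return results
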