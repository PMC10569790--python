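"""End-to-end orchestration: data -> features -> classification -> FC -> report.

``run_pipeline`` drives the whole analysis for a cohort (synthetic scenario
or long-format input file): per-ROI feature extraction for both periods,
well-behaved masking, baseline-subtracted deltas, robust-sigmoid
normalization, repeated-CV SVM classification with permutation inference
and FDR across ROIs, loop-vs-non-loop and hierarchy analyses, feature-level
scores for significant ROIs, and the seed-based functional-connectivity
analysis.  All randomness flows from the master seed; re-running with the
same configuration and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import classify, connectivity, feature_stats, preprocess, synthdata
from .features import default_catalog
from .io import TimeSeriesData, read_time_series
from .statcore import PermutationSpec

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

DEFAULT_CONTRASTS = (("control", "excitation"), ("control", "inhibition"))


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``input_path`` or ``scenario`` must be set.  ``smoke``
    lowers the resampling effort (permutations and CV repeats) for fast
    runs; full mode reproduces the study-scale settings (ten folds, 50
    repeats, 5000 permutations, FDR 0.05, feature top-set at p_fdr < 0.01).
    """

    input_path: str | None = None
    scenario: str | None = None  # "study" or "null"
    out_dir: str = "bolddyn_out"
    seed: int = 0
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    n_folds: int = 10
    n_repeats: int = 50
    n_permutations: int = 5000
    fdr_level: float = 0.05
    feature_fdr: float = 0.01
    top_k: int = 100
    fc_window: int = 60
    # FC permutations are vectorized and cheap; keep full resolution so the
    # p-value floor does not dominate the FDR even in smoke mode
    fc_permutations: int = 5000
    smoke: bool = False
    smoke_permutations: int = 200
    smoke_repeats: int = 5
    roi_categories: Mapping[str, str] = field(default_factory=dict)
    hierarchy_ranks: Mapping[str, int] = field(default_factory=dict)
    stages: tuple[str, ...] = ("classify", "features", "connectivity")

    @property
    def effective_repeats(self) -> int:
        return self.smoke_repeats if self.smoke else self.n_repeats

    @property
    def effective_permutations(self) -> int:
        return self.smoke_permutations if self.smoke else self.n_permutations

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["roi_categories"] = dict(payload["roi_categories"])
        payload["hierarchy_ranks"] = dict(payload["hierarchy_ranks"])
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline output table."""

    classification: pd.DataFrame
    feature_scores: dict[str, pd.DataFrame]
    fc_baseline: pd.DataFrame | None
    fc_delta_tests: pd.DataFrame | None
    summary: dict


def _as_time_series(config: RunConfig) -> TimeSeriesData:
    if (config.input_path is None) == (config.scenario is None):
        raise ValueError("set exactly one of input_path or scenario")
    if config.input_path is not None:
        return read_time_series(config.input_path)
    if config.scenario == "study":
        scfg = synthdata.study_scenario()
    elif config.scenario == "null":
        scfg = synthdata.null_scenario(n_rois=3)
    else:
        raise ValueError(f"unknown scenario: {config.scenario!r}")
    cohort = synthdata.generate_cohort(scfg, seed=config.seed)
    # scenario carries its own ROI annotation
    config.roi_categories = {r.name: r.category for r in scfg.rois}
    config.hierarchy_ranks = {
        r.name: r.hierarchy_rank for r in scfg.rois if r.hierarchy_rank is not None
    }
    return TimeSeriesData(cohort.series, cohort.groups, cohort.behavior)


def _log(msg: str) -> None:
    print(f"[bolddyn] {msg}", file=sys.stderr)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every requested stage and write result tables and a summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    data = _as_time_series(config)
    rois = data.rois
    periods = data.periods
    if not {"baseline", "post"} <= set(periods):
        raise ValueError(f"need 'baseline' and 'post' periods, found {periods}")
    groups = pd.Series(data.groups)
    catalog = default_catalog()
    _log(f"{len(data.animals)} animals, {len(rois)} ROIs, hash {cfg_hash}")

    # feature extraction for every ROI and period
    matrices: dict[tuple[str, str], preprocess.FeatureMatrix] = {}
    for roi in rois:
        for period in ("baseline", "post"):
            series = data.roi_period_series(roi, period)
            if len(series) != len(data.animals):
                missing = sorted(set(data.animals) - set(series))
                raise ValueError(f"missing series for roi={roi} period={period}: {missing}")
            matrices[(roi, period)] = preprocess.build_feature_matrix(
                series, roi, period, data.groups, catalog
            )
    mask = preprocess.well_behaved_mask(matrices.values())
    deltas = {
        roi: preprocess.delta_features(
            matrices[(roi, "post")], matrices[(roi, "baseline")]
        )
        for roi in rois
    }
    _log(f"retained {len(mask)}/{len(catalog)} well-behaved features")

    summary: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_animals": len(data.animals),
        "rois": rois,
        "n_features_retained": int(len(mask)),
        "contrasts": {},
    }
    class_rows: list[dict] = []
    feature_scores: dict[str, pd.DataFrame] = {}
    fc_baseline = fc_delta = None

    if "classify" in config.stages:
        for ci, (g_a, g_b) in enumerate(config.contrasts):
            if not {g_a, g_b} <= set(groups.unique()):
                continue
            contrast = f"{g_a}-vs-{g_b}"
            per_roi = {}
            for roi in rois:
                d = deltas[roi]
                sel = d.groups.isin([g_a, g_b])
                X = d.data.loc[sel, mask]
                Xn, _ = preprocess.normalize_matrix(X)
                per_roi[roi] = (Xn, d.groups[sel].to_numpy())
            spec = PermutationSpec(
                config.effective_permutations, config.seed + 7919 * (ci + 1)
            )
            results = classify.classify_regions(
                per_roi, spec, config.n_folds, config.effective_repeats,
                contrast=contrast, fdr_level=config.fdr_level,
            )
            for roi, res in results.items():
                class_rows.append(
                    {
                        "roi": roi, "contrast": contrast,
                        "bca_mean": res.bca_mean, "p_perm": res.p_perm,
                        "p_fdr": res.p_fdr,
                        "significant": res.p_fdr < config.fdr_level,
                        "category": config.roi_categories.get(roi, ""),
                    }
                )
            csum: dict = {
                "significant_rois": sorted(
                    r for r, res in results.items() if res.p_fdr < config.fdr_level
                ),
                "bca": {r: results[r].bca_mean for r in results},
            }

            # thalamic loop vs non-loop comparison
            cat = config.roi_categories
            loop = [r for r in rois if cat.get(r) == "thalamic-loop"]
            nonloop = [r for r in rois if cat.get(r) == "thalamic-nonloop"]
            if loop and nonloop:
                mwu = classify.compare_bca_sets(
                    [results[r].bca_mean for r in loop],
                    [results[r].bca_mean for r in nonloop],
                )
                csum["loop_vs_nonloop"] = {
                    "u": mwu.u, "z": mwu.z, "p": mwu.p,
                }
            # cortical hierarchy correlation
            ranks = {r: config.hierarchy_ranks[r] for r in rois
                     if r in config.hierarchy_ranks}
            if len(ranks) >= 5:
                rho, p = classify.hierarchy_correlation(
                    {r: results[r].bca_mean for r in ranks}, ranks,
                    seed=config.seed + 11,
                )
                csum["hierarchy_spearman"] = {"rho": rho, "p": p}
            summary["contrasts"][contrast] = csum

            # feature-level scores for significant ROIs of this contrast
            if "features" in config.stages:
                for roi in csum["significant_rois"]:
                    d = deltas[roi]
                    g1 = d.data.loc[d.groups == g_a, mask]
                    g2 = d.data.loc[d.groups == g_b, mask]
                    tbl = feature_stats.score_features(g1, g2)
                    feature_scores[f"{roi}__{contrast}"] = tbl
        classification = pd.DataFrame.from_records(class_rows)
        _write_table(classification, out / "classification.csv", cfg_hash)
        for key, tbl in feature_scores.items():
            safe = key.replace("|", "_").replace("/", "_")
            _write_table(tbl, out / f"feature_scores_{safe}.csv", cfg_hash, index=True)
    else:
        classification = pd.DataFrame()

    if "connectivity" in config.stages:
        seed_rois = [r for r in rois if config.roi_categories.get(r) == "seed"]
        seed_roi = seed_rois[0] if seed_rois else None
        if seed_roi is not None:
            targets = [r for r in rois if r != seed_roi]
            base_means: dict[str, dict[str, float]] = {}
            delta_means: dict[str, dict[str, float]] = {}
            for t in targets:
                base_means[t] = {}
                delta_means[t] = {}
                for a in data.animals:
                    rec = connectivity.fc_record(
                        a, data.groups[a], seed_roi, t,
                        data.series[(a, seed_roi, "baseline")],
                        data.series[(a, t, "baseline")],
                        data.series[(a, seed_roi, "post")],
                        data.series[(a, t, "post")],
                        window=config.fc_window,
                    )
                    base_means[t][a] = rec.baseline_mean
                    delta_means[t][a] = rec.delta_fc
            base_df = pd.DataFrame(base_means).loc[data.animals]
            delta_df = pd.DataFrame(delta_means).loc[data.animals]
            fc_baseline = connectivity.baseline_fc_test(base_df)
            valid_contrasts = [
                c for c in config.contrasts if {c[0], c[1]} <= set(groups.unique())
            ]
            if valid_contrasts:
                fc_delta = connectivity.group_delta_fc_test(
                    delta_df, groups, valid_contrasts,
                    PermutationSpec(config.fc_permutations, config.seed + 13),
                    fdr_level=config.fdr_level,
                )
            _write_table(fc_baseline, out / "fc_baseline.csv", cfg_hash, index=True)
            if fc_delta is not None:
                _write_table(fc_delta, out / "fc_delta_tests.csv", cfg_hash)
            summary["fc"] = {
                "seed": seed_roi,
                "baseline_significant": fc_baseline.index[
                    fc_baseline["significant"]
                ].tolist(),
                "delta_significant": [] if fc_delta is None else [
                    f"{row['contrast']}:{row['pair']}"
                    for _, row in fc_delta.iterrows() if row["significant"]
                ],
            }
            if data.behavior:
                behav = {}
                for t in targets:
                    try:
                        r, p = connectivity.behavior_fc_correlation(
                            data.behavior, delta_means[t]
                        )
                        behav[t] = {"r": r, "p": p}
                    except ValueError:
                        continue
                summary["behavior_fc"] = behav

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    _log(f"wrote {summary_path}")
    return PipelineResult(classification, feature_scores, fc_baseline, fc_delta, summary)
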