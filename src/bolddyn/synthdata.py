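"""Synthetic cohorts with the statistical structure the pipeline analyzes.

The generative model is a multivariate AR(1): each ROI follows
``x_t = phi * x_{t-1} + eps_t`` with a diagonal transition (per-ROI
autocorrelation ``phi``) and innovations correlated across ROIs (pairwise
coupling, i.e. functional connectivity).  Chemogenetic activation is
emulated by switching, at the injection index, the transition coefficient
to ``phi + delta_phi(group, roi)`` and the innovation-correlation matrix to
a group-specific post matrix.  Sessions mirror the study timeline: 2280
samples at 1 s, baseline = samples [0, 900), injection at 900, 240 samples
discarded, post period = samples [1140, 2040).  An optional zero-phase
band-pass (0.01-0.25 Hz, order 2) reproduces the preprocessing of real
BOLD.  Behavior (contraversive-minus-ipsiversive rotations) is generated
from each animal's realized FC change so that behavior-FC correlations are
recoverable.

Baseline parameters are identical across groups, so baseline statistics
are group-exchangeable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .connectivity import fc_per_minute

__all__ = [
    "RoiSpec",
    "SynthConfig",
    "CohortDataset",
    "generate_cohort",
    "study_scenario",
    "null_scenario",
]

SEED_ROI = "CPdm"

LOOP_ROIS = ("VM|CM", "LD", "MD", "PF", "LP", "CL")
NONLOOP_ROIS = (
    "VPL", "RE|LH|RH", "PO|POL", "SPF|SPA|PP", "IMD", "RT", "AM", "VAL|VPM|VPMpc",
)
# transmodal (rank 1) to unimodal (rank 12)
CORTICAL_RANKS = {
    "AI": 1, "PL": 2, "ECT|PERI": 3, "VISC|GU": 4, "ORB": 5, "RSP": 6,
    "MOs": 7, "MOp": 8, "SSp": 9, "ACA": 10, "PTLp": 11, "VIS": 12,
}


@dataclass(frozen=True)
class RoiSpec:
    name: str
    category: str  # seed | thalamic-loop | thalamic-nonloop | cortical
    hierarchy_rank: int | None = None


@dataclass
class SynthConfig:
    """Full description of a synthetic cohort.

    ``delta_phi[group][roi]`` is added to the transition coefficient in the
    post period; ``post_corr[group]`` replaces the baseline innovation
    correlation after the injection.  Stationarity (|phi| < 1 everywhere)
    and positive-definiteness of every correlation matrix are enforced.
    """

    rois: tuple[RoiSpec, ...]
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 10, "excitation": 13, "inhibition": 15}
    )
    session_len: int = 2280
    injection_index: int = 900
    post_skip: int = 240
    period_len: int = 900
    phi0: float = 0.5
    phi_jitter_sd: float = 0.05
    delta_phi: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_corr: np.ndarray | None = None  # rois x rois, unit diagonal
    post_corr: Mapping[str, np.ndarray] = field(default_factory=dict)
    bandpass: bool = True
    band: tuple[float, float] = (0.01, 0.25)
    behavior_pairs: tuple[tuple[str, str], ...] = ()
    behavior_slope: float = 0.0
    behavior_noise_sd: float = 0.0
    burn_in: int = 200

    @property
    def roi_names(self) -> list[str]:
        return [r.name for r in self.rois]

    def dphi(self, group: str, roi: str) -> float:
        return float(self.delta_phi.get(group, {}).get(roi, 0.0))

    def validate(self) -> None:
        if min(self.group_sizes.values()) < 3:
            raise ValueError("each group needs at least 3 animals")
        names = self.roi_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names")
        margin = 3.0 * self.phi_jitter_sd
        for g in self.group_sizes:
            for r in names:
                if abs(self.phi0 + self.dphi(g, r)) + margin >= 1.0:
                    raise ValueError(f"non-stationary configuration for {g}/{r}")
        for c in [self.baseline_corr, *self.post_corr.values()]:
            if c is None:
                continue
            c = np.asarray(c)
            if c.shape != (len(names), len(names)):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrix must be symmetric, unit diagonal")
            np.linalg.cholesky(c)  # raises if not positive definite


@dataclass
class CohortDataset:
    """Generated cohort keyed by (animal, roi, period)."""

    series: dict[tuple[str, str, str], np.ndarray]
    groups: dict[str, str]
    behavior: dict[str, float]
    config: SynthConfig
    seed: int

    @property
    def animals(self) -> list[str]:
        return sorted(self.groups)

    def get(self, animal: str, roi: str, period: str) -> np.ndarray:
        return self.series[(animal, roi, period)]


def _simulate_session(
    rng: np.random.Generator,
    phi_base: np.ndarray,
    phi_post: np.ndarray,
    chol_base: np.ndarray,
    chol_post: np.ndarray,
    cfg: SynthConfig,
) -> np.ndarray:
    """One animal's (session_len x n_rois) multivariate AR(1) session."""
    n_roi = phi_base.size
    total = cfg.burn_in + cfg.session_len
    split = cfg.burn_in + cfg.injection_index
    eps = rng.standard_normal((total, n_roi))
    eps[:split] = eps[:split] @ chol_base.T
    eps[split:] = eps[split:] @ chol_post.T
    x = np.empty((total, n_roi))
    for r in range(n_roi):
        seg1 = signal.lfilter([1.0], [1.0, -phi_base[r]], eps[:split, r])
        zi = [phi_post[r] * seg1[-1]]
        seg2, _ = signal.lfilter([1.0], [1.0, -phi_post[r]], eps[split:, r], zi=zi)
        x[:, r] = np.concatenate([seg1, seg2])
    x = x[cfg.burn_in:]
    if cfg.bandpass:
        sos = signal.butter(2, cfg.band, btype="bandpass", fs=1.0, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=0)
    return x


def generate_cohort(config: SynthConfig, seed: int = 0) -> CohortDataset:
    """Simulate every animal's session and slice it into the two periods."""
    config.validate()
    names = config.roi_names
    n_roi = len(names)
    base_c = (
        np.eye(n_roi) if config.baseline_corr is None
        else np.asarray(config.baseline_corr, dtype=float)
    )
    chol_base = np.linalg.cholesky(base_c)

    root = np.random.SeedSequence(seed)
    series: dict[tuple[str, str, str], np.ndarray] = {}
    groups: dict[str, str] = {}
    behavior: dict[str, float] = {}

    post_start = config.injection_index + config.post_skip
    post_end = post_start + config.period_len

    animal_specs = []
    for group in sorted(config.group_sizes):
        for i in range(config.group_sizes[group]):
            animal_specs.append((f"{group}_{i + 1:02d}", group))
    child_seeds = root.spawn(len(animal_specs))

    for (animal, group), child in zip(animal_specs, child_seeds):
        rng = np.random.default_rng(child)
        phi_base = config.phi0 + rng.normal(0.0, config.phi_jitter_sd, n_roi)
        phi_base = np.clip(phi_base, -0.99, 0.99)
        phi_post = np.clip(
            phi_base + np.array([config.dphi(group, r) for r in names]), -0.99, 0.99
        )
        post_c = np.asarray(config.post_corr.get(group, base_c), dtype=float)
        chol_post = np.linalg.cholesky(post_c)
        x = _simulate_session(rng, phi_base, phi_post, chol_base, chol_post, config)
        groups[animal] = group
        for r, name in enumerate(names):
            series[(animal, name, "baseline")] = x[: config.period_len, r].copy()
            series[(animal, name, "post")] = x[post_start:post_end, r].copy()
        if config.behavior_pairs:
            deltas = []
            for s, t in config.behavior_pairs:
                base_fc = fc_per_minute(
                    series[(animal, s, "baseline")], series[(animal, t, "baseline")]
                )
                post_fc = fc_per_minute(
                    series[(animal, s, "post")], series[(animal, t, "post")]
                )
                deltas.append(np.nanmean(post_fc) - np.nanmean(base_fc))
            behavior[animal] = float(
                config.behavior_slope * np.mean(deltas)
                + rng.normal(0.0, config.behavior_noise_sd)
            )
    return CohortDataset(series, groups, behavior, config, seed)


def _star_corr(names: Sequence[str], seed_edges: Mapping[str, float]) -> np.ndarray:
    """Unit-diagonal correlation with couplings only on seed-target edges.

    Positive definite whenever the sum of squared edge weights is below 1.
    """
    n = len(names)
    c = np.eye(n)
    i0 = names.index(SEED_ROI)
    ss = 0.0
    for target, w in seed_edges.items():
        j = names.index(target)
        c[i0, j] = c[j, i0] = w
        ss += w * w
    if ss >= 1.0:
        raise ValueError("seed couplings too strong for positive definiteness")
    return c


# edges perturbed by the excitation/inhibition manipulations
PERTURBED_EDGES = ("ACA", "MOp", "RSP")


def study_scenario() -> SynthConfig:
    """Default scenario reproducing the study's qualitative effect pattern.

    * Excitation raises the post-period autocorrelation by +0.2 in the seed
      and the loop-forming thalamic ROIs (+0.1 under inhibition), leaves
      non-loop thalamic ROIs untouched, and scales the cortical effect
      linearly with hierarchy rank so unimodal areas (highest rank) change
      most.
    * Baseline coupling links the seed to a few cortical/thalamic partners;
      excitation removes 0.3 from the seed-(ACA, MOp, RSP) edges and
      inhibition adds 0.15.
    * Behavior follows the realized seed-cortical FC change with a negative
      slope (reduced FC under excitation goes with more contraversive
      rotation) plus noise.
    """
    rois = [RoiSpec(SEED_ROI, "seed")]
    rois += [RoiSpec(n, "thalamic-loop") for n in LOOP_ROIS]
    rois += [RoiSpec(n, "thalamic-nonloop") for n in NONLOOP_ROIS]
    rois += [RoiSpec(n, "cortical", rank) for n, rank in CORTICAL_RANKS.items()]
    names = [r.name for r in rois]

    exc: dict[str, float] = {SEED_ROI: 0.2}
    inh: dict[str, float] = {SEED_ROI: 0.1}
    for n in LOOP_ROIS:
        exc[n] = 0.2
        inh[n] = 0.1
    for n, rank in CORTICAL_RANKS.items():
        exc[n] = 0.15 * rank / 12.0
        inh[n] = 0.075 * rank / 12.0

    base_edges = {"ACA": 0.3, "MOp": 0.3, "RSP": 0.3, "PL": 0.15,
                  "VM|CM": -0.15, "VAL|VPM|VPMpc": -0.15}
    exc_edges = dict(base_edges)
    inh_edges = dict(base_edges)
    for t in PERTURBED_EDGES:
        exc_edges[t] = base_edges[t] - 0.3
        inh_edges[t] = base_edges[t] + 0.15

    return SynthConfig(
        rois=tuple(rois),
        delta_phi={"excitation": exc, "inhibition": inh},
        baseline_corr=_star_corr(names, base_edges),
        post_corr={
            "control": _star_corr(names, base_edges),
            "excitation": _star_corr(names, exc_edges),
            "inhibition": _star_corr(names, inh_edges),
        },
        behavior_pairs=tuple((SEED_ROI, t) for t in PERTURBED_EDGES),
        behavior_slope=-100.0,
        behavior_noise_sd=8.0,
    )


def null_scenario(n_rois: int = 1, groups: Mapping[str, int] | None = None) -> SynthConfig:
    """No-effect scenario: identical dynamics in every group and period."""
    rois = tuple(RoiSpec(f"roi_{i + 1}", "thalamic-nonloop") for i in range(n_rois))
    cfg = SynthConfig(rois=rois)
    if groups is not None:
        cfg = replace(cfg, group_sizes=dict(groups))
    return cfg
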