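# Methods

## Scientific setting

`bolddyn` analyzes regional resting-state BOLD dynamics under a chemogenetic
(DREADD) manipulation with a baseline/post design: each animal contributes,
for every region of interest (ROI), a 900-sample baseline series and a
900-sample post-activation series sampled at 1 s (sessions of 2280 samples
with the activating injection at sample 900 and the following 240 samples
discarded while the actuator takes effect). The questions the pipeline
answers are (i) in which ROIs the *within-region* dynamics change enough to
distinguish modulated from control animals, (ii) *which* time-series
properties carry that change, and (iii) how *between-region* coupling
(functional connectivity, FC) changes.

## Feature-based classification

Each series is summarized by a curated catalogue of 36 named time-series
features spanning nine families: distribution moments, linear
autocorrelation (lags 1–10, first zero/1-e crossings and the integrated
autocorrelation time), automutual information, Fourier spectral summaries
(low-frequency power fraction, centroid, spectral entropy),
autoregressive-model fits (Yule–Walker AR(2) coefficients, innovation
variance, AIC-selected order ≤ 8), detrended fluctuation analysis, entropy
(sample entropy m=2, r=0.2·SD; permutation entropy order 3), stationarity
(StatAv with 5 and 10 segments) and outlier statistics. The catalogue is a
compact stand-in for exhaustive feature libraries of thousands of
statistics; the classification pipeline is feature-set-agnostic, so the
catalogue can be swapped without touching the inference machinery.

Fixed numerical conventions (so results reproduce bit for bit): biased
(divisor-n) autocorrelation estimates; all families except the distribution
moments are computed on the z-scored series, which makes them invariant to
affine transforms of the raw signal; automutual information uses
equiprobable (rank-quantile) bins, in nats, and is therefore invariant to
monotone transforms; non-finite feature values are flagged rather than
raised, and removal of such "poorly behaved" features is a separate,
shared-mask step (a feature is kept only if finite for every animal, ROI
and period entering an analysis, and non-constant across animals).

Classification works on the *change* of each feature: post minus baseline,
per animal, which also cancels stable between-animal differences. Each
feature column of the delta matrix is normalized with an outlier-robust
sigmoid `x -> 1/(1 + exp(-(x - median)/(1.35*IQR)))`, fitted jointly on the
two groups being classified (the scale constant times the IQR makes the
transition wider than one Gaussian SD; zero-IQR columns are dropped rather
than imputed). Normalization is deliberately fitted once per contrast, not
per CV fold — it uses no label information; a per-fold refit is a
straightforward variant for leakage-sensitive applications.

The classifier is a linear SVM (cost C = 1, not tuned) with
inverse-probability class reweighting (weight N/(2·n_c) for class c) to
handle the 10-control vs 13/15-modulated imbalance. Performance is the
balanced classification accuracy, BCA = 100·(sensitivity + specificity)/2,
from stratified ten-fold cross-validation: held-out predictions are pooled
across the ten folds of one partition before computing BCA (robust to folds
holding a single class member, which these group sizes force), and BCA is
averaged over repeated random partitions (50 at full scale). Folds whose
training set loses a class trigger a bounded partition redraw.

Significance per ROI comes from a permutation test: group labels are
permuted (class sizes preserved) and the identical repeated-CV procedure is
rerun with the same internal partition seed (paired nulls), 5000 shuffles
at full scale; p-values use the add-one convention
`(1 + #{null >= observed})/(1 + B)` and are corrected across ROIs by
Benjamini–Hochberg FDR at 0.05. An overfitting control refits the SVM in a
PCA space grown one component at a time until the training folds reach 100%
in-sample balanced accuracy, then compares held-out BCA in that reduced
space with the full-space result.

## Rank statistics

The Mann–Whitney U convention: U counts pairs `x_i < y_j` (ties 1/2), the
z statistic uses the tie-corrected variance and *no continuity correction*,
and the exact two-sided p (tie-free data, n1+n2 ≤ 25 by default) is twice
the smaller tail of the fully enumerated null, capped at 1. Both the exact
and the normal-approximation p are exposed because they answer slightly
different needs: the exact tail for tiny samples (e.g. comparing six
loop-forming thalamic ROIs' BCAs with eight non-loop ones), the z for a
bounded, comparable-across-features effect size. The per-feature "feature
score" is this signed z, positive when the stimulation group's values are
larger; scores get BH-FDR across features, the top set (p_FDR < 0.01, up to
100 features) is clustered with average linkage under the absolute-Spearman
distance 1 − |ρ|, and score vectors of two ROIs are compared with a
correlated-shuffle permutation test (one label permutation applied to both
ROIs per shuffle, preserving the within-animal dependence; one-sided for
positive correlation by default, the direction of scientific interest).

Spearman p-values for the hierarchy analysis are exact by enumeration for
n ≤ 8, seeded Monte-Carlo (20 000 permutations, add-one) for 8 < n ≤ 12,
and t-approximate beyond — full enumeration at n = 12 would require ~5·10⁸
permutations for no practical gain in resolution.

## Functional connectivity

FC between the seed (the manipulated striatal region) and each other ROI is
the Pearson correlation per non-overlapping 60-sample (one-minute) window —
15 values per period — averaged per period without Fisher transform (an
option); ΔFC = post − baseline per animal. Baseline FC is tested against
zero with two-sided one-sample Wilcoxon tests (FDR 0.01 across pairs).
Group ΔFC differences use a permutation test on the difference of group
means (two-sided, add-one, FDR jointly over pairs × contrasts at 0.05);
this replaces a GLM with nuisance covariates, which are out of scope here.
FC is plain pairwise Pearson correlation: only seed-to-ROI pairs are
analyzed, where regularized/partial-correlation variants reduce to near-
identical estimates. Behavior (contraversive-minus-ipsiversive rotations)
is related to a pair's ΔFC with a Pearson correlation.

## Synthetic cohorts

The generator is the minimal model producing both tunable regional
autocorrelation and tunable pairwise coupling: a multivariate AR(1) with
diagonal transition `diag(phi)` and innovations drawn with correlation
matrix C, band-pass filtered (0.01–0.25 Hz, zero-phase order-2 Butterworth)
like real BOLD. Neuromodulation is a post-period shift of the transition
coefficient, `phi -> phi + delta_phi(group, roi)`, because autocorrelation-
family features are the discriminative signature of interest; coupling
changes are post-period edits of C. Baseline parameters are identical
across groups, so baseline statistics are group-exchangeable by
construction. Per-animal heterogeneity is a Gaussian phi jitter
(SD 0.05) shared between periods, which the baseline subtraction cancels.

Defaults mirror the study conditions: groups of 10 (control), 13
(excitation) and 15 (inhibition); 27 ROIs — the seed, six loop-forming
thalamic ROIs, eight non-loop thalamic ROIs and twelve cortical ROIs ranked
1 (transmodal) to 12 (unimodal); baseline phi 0.5. The bundled "study"
scenario (`study_scenario()`) sets delta_phi = +0.2 (excitation) / +0.1 (inhibition) in the seed
and loop ROIs, zero in non-loop ROIs, and a cortical effect growing
linearly with hierarchy rank to a maximum of 0.15 (excitation), so unimodal
areas change most; baseline coupling links the seed to a few cortical and
thalamic partners (star structure, positive definite whenever the squared
edge weights sum below 1), excitation removes 0.3 from the seed–(ACA, MOp,
RSP) edges and inhibition adds 0.15. Behavior is generated from each
animal's *realized* FC change (slope −100 rotations per unit ΔFC, noise
SD 8), so behavior–FC correlations are recoverable rather than assumed.
Effect magnitudes are chosen for testability — large enough that the
designed pattern is recoverable at study-scale group sizes, small enough
that null regions stay null; they are not estimates of the real effect
sizes, which are unknown.

What the generator does *not* emulate: hemodynamic response convolution,
physiological noise, motion artifacts, spatial (voxel-level) structure, and
non-AR temporal nonlinearities. Passing recovery tests therefore
demonstrates that the *pipeline* detects the statistical structure it is
designed for, not that real BOLD data contain that structure.

## Problem sizes and numerical choices

Full-scale settings (ten folds, 50 repeats, 5000 permutations) reproduce
study-scale inference; the bundled tests and the acceptance script run
reduced resampling scales chosen as the package's own smoke settings —
null-calibration over 60–100 independent cohorts at 50 permutations and 3
CV repeats each, recovery at 100 permutations and 3 repeats — because the
properties under test (uniformity of null p-values, chance-level BCA, sign
and ordering of designed effects) are invariant to the resampling depth.
FC permutations stay at 5000 even in smoke mode: they are vectorized and
cheap, and a coarser null would put the permutation p-value floor above the
FDR threshold. Monte-Carlo p-values count ties with a 1e-12 absolute
tolerance so statistics recomputed through floating-point paths register
as ties. All randomness derives from a single master seed via seed
sequences; identical configuration and seed reproduce every output byte
for byte.

## Known limitations

* The curated catalogue trades coverage for interpretability; properties
  outside its nine families (wavelets, nonlinear forecasting, long-range
  cross-scale statistics) are invisible to it.
* The permutation test treats animals as exchangeable under the null;
  confounds correlated with group assignment (age, weight, sex) are not
  modeled.
* The exact Mann–Whitney path refuses tied data (it falls back to the
  normal approximation with a warning flag); heavily tied features rely on
  the tie-corrected z.
* With ten folds and ten controls, every partition holds at most one
  control per fold; pooled-BCA is stable under this regime but per-fold BCA
  would not be, which is why it is not offered.
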