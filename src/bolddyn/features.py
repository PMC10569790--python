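"""Curated catalogue of time-series features for regional BOLD dynamics.

A compact, fully documented stand-in for a large automated feature library:
every feature family that has proven discriminative for slow, band-limited
BOLD fluctuations is represented — distribution moments, linear
autocorrelation and correlation timescales, automutual information, Fourier
spectral summaries, autoregressive model fits, detrended fluctuation
analysis, entropy, stationarity, and outlier statistics.

Conventions (fixed so results reproduce bit-for-bit):

* Autocorrelations use the biased (divisor-n) estimator.
* All families except ``distribution`` are computed on the z-scored series.
* Automutual information uses equiprobable (rank-quantile) binning, in nats.
* Non-finite feature outputs are flagged in the returned vector, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal, stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "FeatureSpec",
    "FeatureCatalog",
    "FeatureVector",
    "default_catalog",
    "acf_lag",
    "ac_timescales",
    "integrated_ac_timescale",
    "low_freq_power_fraction",
    "automutual_info",
    "dfa_alpha",
    "sample_entropy",
    "permutation_entropy",
    "stat_av",
    "ar_coefficients",
    "ar_aic_order",
    "extract_feature_vector",
]

FAMILIES = (
    "distribution",
    "autocorrelation",
    "automutual-information",
    "spectral",
    "ar-model",
    "fluctuation",
    "entropy",
    "stationarity",
    "outlier",
)


# ---------------------------------------------------------------------------
# individual feature computations
# ---------------------------------------------------------------------------

def _acf(ts: np.ndarray, nlags: int) -> np.ndarray:
    """Biased (divisor-n) mean-removed autocorrelation function."""
    return _sm_acf(ts, nlags=nlags, fft=True, adjusted=False)


def acf_lag(ts: Sequence[float], lag: int) -> float:
    """Autocorrelation at a single lag (biased estimator); lag 0 gives 1."""
    ts = np.asarray(ts, dtype=float)
    if lag >= ts.size:
        raise ValueError("lag must be smaller than the series length")
    if np.ptp(ts) == 0:
        return float("nan")
    return float(_acf(ts, max(lag, 1))[lag])


def ac_timescales(ts: Sequence[float]) -> tuple[int, int]:
    """First lag where the ACF drops below 0 and below 1/e.

    Lags up to length/4 are scanned; the scan limit is returned when the
    threshold is never crossed.
    """
    ts = np.asarray(ts, dtype=float)
    if np.ptp(ts) == 0:
        raise ValueError("autocorrelation timescales undefined for a constant series")
    max_lag = ts.size // 4
    ac = _acf(ts, max_lag)
    below_zero = np.nonzero(ac[1:] < 0)[0]
    below_1e = np.nonzero(ac[1:] < 1.0 / math.e)[0]
    first_zero = int(below_zero[0]) + 1 if below_zero.size else max_lag
    first_1e = int(below_1e[0]) + 1 if below_1e.size else max_lag
    return first_zero, first_1e


def integrated_ac_timescale(ts: Sequence[float]) -> float:
    """Integrated autocorrelation time ``1 + 2 * sum ACF(k)`` up to first zero.

    A continuous-valued correlation-timescale estimate: for an AR(1) process
    with coefficient phi it approaches ``(1 + phi) / (1 - phi)``.  Summation
    stops at the first negative ACF value (or length/4).
    """
    ts = np.asarray(ts, dtype=float)
    if np.ptp(ts) == 0:
        raise ValueError("timescale undefined for a constant series")
    max_lag = ts.size // 4
    ac = _acf(ts, max_lag)
    below = np.nonzero(ac[1:] < 0)[0]
    stop = int(below[0]) + 1 if below.size else max_lag
    return float(1.0 + 2.0 * ac[1:stop].sum())


def low_freq_power_fraction(
    ts: Sequence[float],
    fs: float = 1.0,
    band: tuple[float, float] = (0.01, 0.1),
    total_band: tuple[float, float] = (0.01, 0.25),
) -> float:
    """Fraction of periodogram power in ``band`` relative to ``total_band``.

    An fALFF-like statistic: with the defaults it is low-frequency
    (0.01-0.1 Hz) power over the full analysis band (0.01-0.25 Hz) of
    band-passed BOLD sampled at 1 Hz.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.size < 64:
        raise ValueError("series too short for a stable periodogram")
    freqs, pxx = signal.periodogram(ts, fs=fs, detrend="constant")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_total = (freqs >= total_band[0]) & (freqs <= total_band[1])
    denom = pxx[in_total].sum()
    if denom <= 0:
        return float("nan")
    return float(pxx[in_band].sum() / denom)


def _equiprobable_bins(ts: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to one of n_bins rank-quantile bins (0..n_bins-1)."""
    ranks = stats.rankdata(ts, method="average")
    b = np.floor((ranks - 0.5) / ts.size * n_bins).astype(int)
    return np.clip(b, 0, n_bins - 1)


def automutual_info(ts: Sequence[float], lag: int, n_bins: int = 10) -> float:
    """Histogram automutual information (nats) with equiprobable binning.

    Equiprobable bins make the estimate invariant to monotone transforms of
    the series; identity coupling returns the marginal entropy log(n_bins).
    """
    ts = np.asarray(ts, dtype=float)
    if lag < 1 or ts.size - lag < 2 * n_bins:
        raise ValueError("series too short for the requested lag/binning")
    if np.ptp(ts) == 0:
        return float("nan")
    b = _equiprobable_bins(ts, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (b[:-lag], b[lag:]), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz]))
    return float(max(mi, 0.0))


def dfa_alpha(
    ts: Sequence[float], window_range: tuple[int, int] = (10, 100), n_windows: int = 20
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Integrates the mean-removed series, splits it into non-overlapping
    windows of log-spaced sizes, removes a linear trend per window and fits
    the slope of log F(n) versus log n.  White noise gives alpha ~ 0.5, its
    cumulative sum ~ 1.5.
    """
    ts = np.asarray(ts, dtype=float)
    lo, hi = window_range
    if ts.size < 4 * hi:
        return float("nan")
    if np.ptp(ts) == 0:
        return float("nan")
    y = np.cumsum(ts - ts.mean())
    sizes = np.unique(np.geomspace(lo, hi, n_windows).astype(int))
    fluct = np.empty(sizes.size)
    for i, n in enumerate(sizes):
        k = y.size // n
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        # least-squares linear detrend per segment, vectorized
        t_mean = t.mean()
        s_mean = seg.mean(axis=1, keepdims=True)
        beta = ((seg - s_mean) @ (t - t_mean)) / np.sum((t - t_mean) ** 2)
        resid = seg - s_mean - beta[:, None] * (t - t_mean)
        fluct[i] = math.sqrt(np.mean(resid**2))
    slope = np.polyfit(np.log(sizes), np.log(fluct), 1)[0]
    return float(slope)


def sample_entropy(ts: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r·SD): -ln(A/B) of template-match counts.

    ``r`` is expressed as a fraction of the series SD.  Self-matches are
    excluded; returns NaN when no (m+1)-length templates match.
    """
    ts = np.asarray(ts, dtype=float)
    sd = ts.std()
    if sd == 0 or ts.size < 10 * (m + 1):
        return float("nan")
    tol = r * sd
    # pairwise |x_i - x_j| once; the Chebyshev distance between the m-length
    # templates starting at i and j is max_k d0[i+k, j+k]
    d0 = np.abs(ts[:, None] - ts[None, :])
    dm = d0
    for k in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d0[k:, k:])
    dm1 = np.maximum(dm[:-1, :-1], d0[m:, m:])
    # matrices are symmetric with zero diagonal (self-matches): count the
    # strict upper triangle as (total - diagonal) / 2
    b = (int(np.count_nonzero(dm <= tol)) - dm.shape[0]) // 2
    a = (int(np.count_nonzero(dm1 <= tol)) - dm1.shape[0]) // 2
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def permutation_entropy(ts: Sequence[float], order: int = 3) -> float:
    """Shannon entropy (nats) of ordinal patterns of the given order."""
    ts = np.asarray(ts, dtype=float)
    if ts.size < 10 * math.factorial(order):
        return float("nan")
    if np.ptp(ts) == 0:
        return float("nan")
    emb = np.lib.stride_tricks.sliding_window_view(ts, order)
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each ordinal pattern as an integer
    codes = patterns @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def stat_av(ts: Sequence[float], n_segments: int = 5) -> float:
    """StatAv stationarity index: SD of segment means over the overall SD."""
    ts = np.asarray(ts, dtype=float)
    sd = ts.std()
    if sd == 0 or ts.size < 2 * n_segments:
        return float("nan")
    k = ts.size // n_segments
    means = ts[: k * n_segments].reshape(n_segments, k).mean(axis=1)
    return float(means.std() / sd)


def _biased_acov(ts: np.ndarray, nlags: int) -> np.ndarray:
    x = ts - ts.mean()
    n = x.size
    return np.array([np.dot(x[: n - k], x[k:]) / n for k in range(nlags + 1)])


def _levinson(acov: np.ndarray, max_order: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Levinson-Durbin recursion: AR coefficients and innovation variance per order."""
    phi = np.zeros((max_order + 1, max_order + 1))
    sigma2 = np.zeros(max_order + 1)
    sigma2[0] = acov[0]
    coeffs: list[np.ndarray] = [np.array([])]
    for k in range(1, max_order + 1):
        num = acov[k] - np.dot(phi[k - 1, 1:k], acov[1:k][::-1])
        rc = num / sigma2[k - 1]
        phi[k, k] = rc
        phi[k, 1:k] = phi[k - 1, 1:k] - rc * phi[k - 1, 1:k][::-1]
        sigma2[k] = sigma2[k - 1] * (1 - rc**2)
        coeffs.append(phi[k, 1 : k + 1].copy())
    return coeffs, sigma2


def ar_coefficients(ts: Sequence[float], order: int = 2) -> tuple[np.ndarray, float]:
    """Yule-Walker AR(order) coefficients and innovation variance (biased acov)."""
    ts = np.asarray(ts, dtype=float)
    acov = _biased_acov(ts, order)
    if acov[0] == 0:
        return np.full(order, np.nan), float("nan")
    coeffs, sigma2 = _levinson(acov, order)
    return coeffs[order], float(sigma2[order])


def ar_aic_order(ts: Sequence[float], max_order: int = 8) -> int:
    """AIC-selected Yule-Walker AR model order in 1..max_order."""
    ts = np.asarray(ts, dtype=float)
    acov = _biased_acov(ts, max_order)
    if acov[0] == 0:
        return -1
    _, sigma2 = _levinson(acov, max_order)
    n = ts.size
    aic = [n * math.log(max(sigma2[k], 1e-300)) + 2 * k for k in range(1, max_order + 1)]
    return int(np.argmin(aic)) + 1


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    feature_id: str
    family: str
    params: Mapping[str, float]
    func: Callable[[np.ndarray], float]


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, deterministic collection of named feature computations."""

    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        ids = [s.feature_id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        missing = set(FAMILIES) - {s.family for s in self.specs}
        if missing:
            raise ValueError(f"empty feature families: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def feature_ids(self) -> list[str]:
        return [s.feature_id for s in self.specs]

    def to_table(self) -> "pd.DataFrame":  # noqa: F821 - local import
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": [s.feature_id for s in self.specs],
                "family": [s.family for s in self.specs],
                "params": [
                    ";".join(f"{k}={v}" for k, v in sorted(s.params.items()))
                    for s in self.specs
                ],
            }
        )


@dataclass(frozen=True)
class FeatureVector:
    """Feature values aligned to a catalogue, with finiteness flags."""

    values: np.ndarray
    finite: np.ndarray
    feature_ids: tuple[str, ...]


def default_catalog() -> FeatureCatalog:
    """The default ~35-feature catalogue covering all nine families."""
    specs: list[FeatureSpec] = []

    def add(fid: str, family: str, params: Mapping[str, float], func) -> None:
        specs.append(FeatureSpec(fid, family, dict(params), func))

    # distribution family (computed on the raw series)
    add("mean", "distribution", {}, lambda x: float(np.mean(x)))
    add("std", "distribution", {}, lambda x: float(np.std(x, ddof=1)))
    add("skewness", "distribution", {}, lambda x: float(stats.skew(x)))
    add("kurtosis", "distribution", {}, lambda x: float(stats.kurtosis(x)))
    add("median", "distribution", {}, lambda x: float(np.median(x)))
    add("iqr", "distribution", {}, lambda x: float(stats.iqr(x)))

    # linear autocorrelation
    for lag in range(1, 11):
        add(f"ac_{lag}", "autocorrelation", {"lag": lag},
            lambda x, lag=lag: acf_lag(x, lag))
    add("first_zero_ac", "autocorrelation", {}, lambda x: float(ac_timescales(x)[0]))
    add("first_1e_ac", "autocorrelation", {}, lambda x: float(ac_timescales(x)[1]))
    add("ac_timescale", "autocorrelation", {}, integrated_ac_timescale)

    # automutual information
    for lag in (1, 2):
        add(f"ami_{lag}", "automutual-information", {"lag": lag, "n_bins": 10},
            lambda x, lag=lag: automutual_info(x, lag, 10))

    # spectral
    add("low_freq_power", "spectral",
        {"f_lo": 0.01, "f_hi": 0.1, "F_lo": 0.01, "F_hi": 0.25},
        lambda x: low_freq_power_fraction(x))
    add("spectral_centroid", "spectral", {"F_lo": 0.01, "F_hi": 0.25},
        _spectral_centroid)
    add("spectral_entropy", "spectral", {"F_lo": 0.01, "F_hi": 0.25},
        _spectral_entropy)

    # AR-model fits
    add("ar2_coef1", "ar-model", {"order": 2}, lambda x: float(ar_coefficients(x, 2)[0][0]))
    add("ar2_coef2", "ar-model", {"order": 2}, lambda x: float(ar_coefficients(x, 2)[0][1]))
    add("ar2_resid_var", "ar-model", {"order": 2}, lambda x: ar_coefficients(x, 2)[1])
    add("ar_aic_order", "ar-model", {"max_order": 8}, lambda x: float(ar_aic_order(x, 8)))

    # fluctuation analysis
    add("dfa_alpha", "fluctuation", {"w_min": 10, "w_max": 100},
        lambda x: dfa_alpha(x, (10, 100)))
    add("dfa_alpha_long", "fluctuation", {"w_min": 25, "w_max": 200},
        lambda x: dfa_alpha(x, (25, 200)))

    # entropy
    add("sample_entropy", "entropy", {"m": 2, "r": 0.2}, lambda x: sample_entropy(x))
    add("perm_entropy", "entropy", {"order": 3}, lambda x: permutation_entropy(x))

    # stationarity
    add("stat_av_5", "stationarity", {"n_segments": 5}, lambda x: stat_av(x, 5))
    add("stat_av_10", "stationarity", {"n_segments": 10}, lambda x: stat_av(x, 10))

    # outliers (on the z-scored series)
    add("max_abs_z", "outlier", {}, lambda x: float(np.max(np.abs(x))))
    add("frac_abs_z_gt2", "outlier", {"threshold": 2.0},
        lambda x: float(np.mean(np.abs(x) > 2.0)))

    return FeatureCatalog(tuple(specs))


def _spectral_centroid(ts: np.ndarray) -> float:
    freqs, pxx = signal.periodogram(ts, fs=1.0, detrend="constant")
    m = (freqs >= 0.01) & (freqs <= 0.25)
    tot = pxx[m].sum()
    if tot <= 0:
        return float("nan")
    return float(np.sum(freqs[m] * pxx[m]) / tot)


def _spectral_entropy(ts: np.ndarray) -> float:
    freqs, pxx = signal.periodogram(ts, fs=1.0, detrend="constant")
    m = (freqs >= 0.01) & (freqs <= 0.25)
    p = pxx[m]
    tot = p.sum()
    if tot <= 0:
        return float("nan")
    p = p / tot
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])) / math.log(nz.sum()))


def extract_feature_vector(
    ts: Sequence[float], catalog: FeatureCatalog | None = None
) -> FeatureVector:
    """Compute every catalogue feature on one series.

    The distribution family sees the raw series; all other families see the
    z-scored series.  A feature that fails or returns a non-finite value is
    recorded as NaN with its finiteness flag cleared — filtering poorly
    behaved features is a separate pipeline step.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.size < 128:
        raise ValueError("series must have at least 128 samples")
    if catalog is None:
        catalog = default_catalog()
    import warnings

    sd = ts.std()
    z = (ts - ts.mean()) / sd if sd > 0 else None
    values = np.empty(len(catalog))
    for i, spec in enumerate(catalog.specs):
        if spec.family != "distribution" and z is None:
            values[i] = float("nan")  # degenerate input: flag, don't compute
            continue
        x = ts if spec.family == "distribution" else z
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = spec.func(x)
        except Exception:
            v = float("nan")
        values[i] = v if np.isfinite(v) else float("nan")
    finite = np.isfinite(values)
    return FeatureVector(values, finite, tuple(catalog.feature_ids))
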