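"""Feature computations against closed forms and Monte-Carlo oracles."""

import numpy as np
import pytest

from bolddyn.features import (
    ac_timescales,
    acf_lag,
    integrated_ac_timescale,
    ar_aic_order,
    ar_coefficients,
    automutual_info,
    default_catalog,
    dfa_alpha,
    extract_feature_vector,
    low_freq_power_fraction,
    permutation_entropy,
    sample_entropy,
    stat_av,
)

from conftest import ar1


def test_acf_alternating_and_lag_zero(rng):
    alt = np.tile([1.0, -1.0], 50)
    assert acf_lag(alt, 1) == pytest.approx(-0.99)
    assert acf_lag(rng.normal(size=100), 0) == pytest.approx(1.0)


def test_acf_ar1_recovers_phi(rng):
    x = ar1(0.6, 100_000, rng)
    assert acf_lag(x, 1) == pytest.approx(0.6, abs=0.01)


def test_ac_timescales(rng):
    alt = np.tile([1.0, -1.0], 50)
    assert ac_timescales(alt)[0] == 1
    x = ar1(0.8, 100_000, rng)
    # phi^5 = 0.328 < 1/e <= phi^4
    assert ac_timescales(x)[1] == 5
    hits = sum(ac_timescales(ar1(0.0, 2000, rng))[0] <= 3 for _ in range(10))
    assert hits >= 8
    with pytest.raises(ValueError):
        ac_timescales(np.ones(100))


def test_integrated_timescale_matches_ar1_closed_form(rng):
    """Integrated autocorrelation time of AR(1) approaches (1+phi)/(1-phi)."""
    for phi in (0.3, 0.6):
        x = ar1(phi, 200_000, rng)
        expected = (1 + phi) / (1 - phi)
        assert integrated_ac_timescale(x) == pytest.approx(expected, rel=0.05)


def test_low_freq_power_fraction(rng):
    t = np.arange(900.0)
    assert low_freq_power_fraction(np.sin(2 * np.pi * 0.05 * t)) > 0.99
    assert low_freq_power_fraction(np.sin(2 * np.pi * 0.2 * t)) < 0.01
    w = rng.normal(size=200_000)
    assert low_freq_power_fraction(w) == pytest.approx(0.09 / 0.24, abs=0.05)


def test_automutual_info_identity_and_invariance(rng):
    # period-100 series: ts(t+100) = ts(t) exactly, so the lag-100 joint
    # distribution is the identity coupling and MI equals log(n_bins)
    base = rng.normal(size=100)
    ts = np.tile(base, 10)
    assert automutual_info(ts, lag=100, n_bins=10) == pytest.approx(np.log(10))
    x = rng.normal(size=3000)
    mi = automutual_info(x, 1)
    assert automutual_info(np.exp(x), 1) == pytest.approx(mi)  # rank invariance
    # independent pairs: MI below a shuffle-based bias threshold
    shuffles = [automutual_info(rng.permutation(x), 1) for _ in range(20)]
    assert mi <= np.max(shuffles) + 0.01


def test_dfa_alpha_theory(rng):
    w = rng.normal(size=10_000)
    assert dfa_alpha(w) == pytest.approx(0.5, abs=0.1)
    assert dfa_alpha(np.cumsum(w)) == pytest.approx(1.5, abs=0.1)
    assert dfa_alpha(5.0 * w) == pytest.approx(dfa_alpha(w), abs=1e-9)
    assert np.isnan(dfa_alpha(w[:200]))  # too short for the window range


def test_ar_fits(rng):
    x = ar1(0.5, 100_000, rng)
    coefs, s2 = ar_coefficients(x, 2)
    assert coefs[0] == pytest.approx(0.5, abs=0.05)
    assert coefs[1] == pytest.approx(0.0, abs=0.05)
    assert s2 == pytest.approx(1.0, abs=0.05)
    assert 1 <= ar_aic_order(x) <= 8


def test_stat_av_white_noise(rng):
    # SD of 5 segment means of 180 samples each: ~ 1/sqrt(180) = 0.0745
    vals = [stat_av(rng.normal(size=900), 5) for _ in range(30)]
    assert np.mean(vals) == pytest.approx(1 / np.sqrt(180), rel=0.5)


def test_entropy_features_behave(rng):
    x = rng.normal(size=900)
    se = sample_entropy(x)
    assert se > 0
    # regular signal is more predictable than noise
    assert sample_entropy(np.sin(2 * np.pi * 0.02 * np.arange(900.0))) < se
    pe = permutation_entropy(x, 3)
    assert 0 < pe <= np.log(6) + 1e-9


def test_catalog_contract():
    cat = default_catalog()
    assert len(cat) >= 30
    assert len(set(cat.feature_ids)) == len(cat)
    fams = {s.family for s in cat.specs}
    assert len(fams) == 9
    tbl = cat.to_table()
    assert list(tbl.columns) == ["feature_id", "family", "params"]
    assert len(tbl) == len(cat)


def test_extract_vector_determinism_and_affine_invariance(rng):
    x = ar1(0.4, 900, rng)
    cat = default_catalog()
    fv1 = extract_feature_vector(x, cat)
    fv2 = extract_feature_vector(x, cat)
    np.testing.assert_array_equal(fv1.values, fv2.values)
    fv3 = extract_feature_vector(3.0 * x + 2.0, cat)
    dist = [s.family == "distribution" for s in cat.specs]
    keep = ~np.asarray(dist)
    np.testing.assert_allclose(fv3.values[keep], fv1.values[keep], rtol=1e-8)


def test_extract_vector_constant_series_flags():
    fv = extract_feature_vector(np.ones(900))
    by_id = dict(zip(fv.feature_ids, fv.finite))
    assert by_id["mean"] and by_id["median"]
    assert not by_id["ac_1"] and not by_id["sample_entropy"]
    assert not by_id["first_1e_ac"] and not by_id["ami_1"]


def test_extract_vector_rejects_short_series():
    with pytest.raises(ValueError):
        extract_feature_vector(np.zeros(100))


def test_autocorrelation_features_increase_with_phi(rng):
    """Larger AR coefficients give slower, more autocorrelated dynamics."""
    ac1s, t1es, lfps = [], [], []
    for phi in (0.2, 0.5, 0.8):
        x = ar1(phi, 50_000, rng)
        ac1s.append(acf_lag(x, 1))
        t1es.append(ac_timescales(x)[1])
        lfps.append(low_freq_power_fraction(x))
    assert ac1s == sorted(ac1s)
    assert t1es == sorted(t1es)
    assert lfps == sorted(lfps)
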