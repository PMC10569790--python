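"""Feature scores, similarity clustering and the correlated-shuffle test."""

import numpy as np
import pandas as pd
import pytest

from bolddyn.feature_stats import (
    cluster_top_features,
    cross_region_score_correlation,
    ranksum_z_scores,
    score_features,
)
from bolddyn.statcore import PermutationSpec


def _groups(rng, n1=10, n2=13, f=5):
    g1 = pd.DataFrame(rng.normal(size=(n1, f)),
                      columns=[f"f{i}" for i in range(f)])
    g2 = pd.DataFrame(rng.normal(size=(n2, f)), columns=g1.columns)
    return g1, g2


def test_swapping_groups_negates_scores(rng):
    g1, g2 = _groups(rng)
    fwd = score_features(g1, g2)["score"]
    rev = score_features(g2, g1)["score"]
    np.testing.assert_allclose(fwd, -rev, atol=1e-12)


def test_complete_separation_score_closed_form(rng):
    """U = 0 at n = 10 vs 13 gives |z| = 65 / sqrt(260)."""
    g1, g2 = _groups(rng)
    g2["f0"] = g1["f0"].max() + 1 + np.arange(13)  # stimulation group larger
    tbl = score_features(g1, g2)
    assert tbl.loc["f0", "score"] == pytest.approx(65 / np.sqrt(260))
    assert tbl.loc["f0", "score"] > 0  # positive = stimulation larger
    assert tbl.loc["f0", "p_fdr"] >= tbl.loc["f0", "p"]


def test_null_feature_scores_calibrated(rng):
    """Identically distributed groups: about 5% of raw p-values below 0.05."""
    hits, total = 0, 0
    for _ in range(40):
        g1, g2 = _groups(rng, f=20)
        p = score_features(g1, g2)["p"]
        hits += (p < 0.05).sum()
        total += p.size
    assert hits / total == pytest.approx(0.05, abs=0.025)


def test_degenerate_columns_flagged(rng):
    g1, g2 = _groups(rng, f=2)
    g1["f0"] = 1.0
    g2["f0"] = 1.0
    tbl = score_features(g1, g2)
    assert np.isnan(tbl.loc["f0", "score"])
    assert np.isfinite(tbl.loc["f1", "score"])


class TestClusterTopFeatures:
    def test_monotone_copy_and_sign_flip_at_zero_distance(self, rng):
        a = rng.normal(size=40)
        vals = pd.DataFrame({"a": a, "b": np.exp(a), "c": -a,
                             "d": rng.normal(size=40)})
        sim = cluster_top_features(vals)
        assert sim.distance.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert sim.distance.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_features_near_maximal_distance(self, rng):
        vals = pd.DataFrame(rng.normal(size=(300, 4)),
                            columns=list("abcd"))
        sim = cluster_top_features(vals)
        off = sim.distance.to_numpy()[np.triu_indices(4, 1)]
        assert np.all(off > 0.8)

    def test_leaf_order_and_newick(self, rng):
        vals = pd.DataFrame(rng.normal(size=(30, 5)),
                            columns=list("abcde"))
        sim = cluster_top_features(vals)
        assert sorted(sim.leaf_order) == list("abcde")
        nwk = sim.to_newick()
        assert nwk.endswith(";") and nwk.count(",") == 4
        clusters = sim.flat_clusters(0.43)
        assert set(clusters.index) == set("abcde")

    def test_constant_feature_excluded(self, rng):
        vals = pd.DataFrame({"a": rng.normal(size=20),
                             "b": rng.normal(size=20),
                             "flat": np.ones(20)})
        sim = cluster_top_features(vals)
        assert sim.excluded == ["flat"]


class TestCrossRegionScoreCorrelation:
    def test_duplicated_region_is_sharp_oracle(self, rng):
        """Identical regions: rho = 1, every null rho = 1, p at the add-one max."""
        d1 = pd.DataFrame(rng.normal(size=(23, 10)),
                          columns=[f"f{i}" for i in range(10)])
        labels = ["control"] * 10 + ["excitation"] * 13
        rho, p, null = cross_region_score_correlation(
            d1, d1.copy(), labels, PermutationSpec(50, 0)
        )
        assert rho == pytest.approx(1.0)
        np.testing.assert_allclose(null, 1.0)
        assert p == 1.0

    def test_null_regions_rho_centered_on_zero(self, rng):
        d1 = pd.DataFrame(rng.normal(size=(23, 15)),
                          columns=[f"f{i}" for i in range(15)])
        d2 = pd.DataFrame(rng.normal(size=(23, 15)), columns=d1.columns)
        labels = ["control"] * 10 + ["excitation"] * 13
        rho, p, null = cross_region_score_correlation(
            d1, d2, labels, PermutationSpec(100, 1)
        )
        assert abs(rho) < 0.8
        assert p > 1 / 101  # not an extreme of its own null

    def test_animal_mismatch_errors(self, rng):
        d1 = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        d2 = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdeg"))
        with pytest.raises(ValueError):
            cross_region_score_correlation(
                d1, d2, ["x"] * 3 + ["y"] * 3, PermutationSpec(10, 0)
            )


def test_ranksum_z_matches_statcore(rng):
    from bolddyn.statcore import mann_whitney

    X = rng.normal(size=(20, 6))
    y = np.r_[np.zeros(9, int), np.ones(11, int)]
    z = ranksum_z_scores(X, y)
    for j in range(6):
        ref = mann_whitney(X[y == 0, j], X[y == 1, j])
        assert z[j] == pytest.approx(ref.z)
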