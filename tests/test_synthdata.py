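"""Synthetic cohort generator: determinism, target statistics, effect links."""

import numpy as np
import pytest

from bolddyn.connectivity import fc_per_minute
from bolddyn.synthdata import (
    RoiSpec,
    SynthConfig,
    generate_cohort,
    null_scenario,
    study_scenario,
)


def _ac1(x):
    return np.corrcoef(x[:-1], x[1:])[0, 1]


def test_same_seed_bit_identical():
    cfg = null_scenario(n_rois=2, groups={"control": 4, "excitation": 4})
    a = generate_cohort(cfg, seed=9)
    b = generate_cohort(cfg, seed=9)
    assert a.series.keys() == b.series.keys()
    for k in a.series:
        np.testing.assert_array_equal(a.series[k], b.series[k])
    c = generate_cohort(cfg, seed=10)
    assert not np.array_equal(a.series[k], c.series[k])


def test_unfiltered_ar1_recovers_phi():
    cfg = SynthConfig(
        rois=(RoiSpec("r", "thalamic-nonloop"),),
        group_sizes={"control": 12, "excitation": 3},
        phi0=0.6, phi_jitter_sd=0.0, bandpass=False,
    )
    coh = generate_cohort(cfg, seed=4)
    ac1s = [_ac1(coh.get(a, "r", "post"))
            for a in coh.animals if coh.groups[a] == "control"]
    assert np.mean(ac1s) == pytest.approx(0.6, abs=0.02)


def test_session_slicing_shapes():
    cfg = null_scenario(n_rois=1, groups={"control": 3, "excitation": 3})
    coh = generate_cohort(cfg, seed=0)
    for (_, _, period), ts in coh.series.items():
        assert ts.shape == (900,)


def test_nonstationary_config_rejected():
    cfg = SynthConfig(
        rois=(RoiSpec("r", "seed"),),
        phi0=0.9,
        delta_phi={"excitation": {"r": 0.2}},
    )
    with pytest.raises(ValueError, match="non-stationary"):
        generate_cohort(cfg, seed=0)


def test_invalid_correlation_rejected():
    bad = np.array([[1.0, 1.2], [1.2, 1.0]])  # not positive definite
    cfg = SynthConfig(
        rois=(RoiSpec("a", "seed"), RoiSpec("b", "cortical", 1)),
        baseline_corr=bad,
    )
    with pytest.raises(np.linalg.LinAlgError):
        generate_cohort(cfg, seed=0)


def test_baseline_statistics_group_exchangeable():
    """No baseline group effect by construction."""
    from bolddyn.statcore import mann_whitney

    coh = generate_cohort(study_scenario(), seed=3)
    ctl = [_ac1(coh.get(a, "VM|CM", "baseline"))
           for a in coh.animals if coh.groups[a] == "control"]
    exc = [_ac1(coh.get(a, "VM|CM", "baseline"))
           for a in coh.animals if coh.groups[a] == "excitation"]
    assert mann_whitney(ctl, exc).p > 0.05


def test_delta_phi_increases_ac1_and_coupling_changes_fc():
    """The causal chain: phi shift raises post AC(1); coupling drop lowers FC."""
    coh = generate_cohort(study_scenario(), seed=2)

    def mean_delta_ac1(roi, group):
        return np.mean([
            _ac1(coh.get(a, roi, "post")) - _ac1(coh.get(a, roi, "baseline"))
            for a in coh.animals if coh.groups[a] == group
        ])

    assert mean_delta_ac1("VM|CM", "excitation") > mean_delta_ac1("VM|CM", "control") + 0.02
    assert abs(mean_delta_ac1("VPL", "excitation") - mean_delta_ac1("VPL", "control")) < 0.02

    def mean_dfc(group):
        out = []
        for a in (a for a in coh.animals if coh.groups[a] == group):
            b = np.nanmean(fc_per_minute(coh.get(a, "CPdm", "baseline"),
                                         coh.get(a, "ACA", "baseline")))
            p = np.nanmean(fc_per_minute(coh.get(a, "CPdm", "post"),
                                         coh.get(a, "ACA", "post")))
            out.append(p - b)
        return np.mean(out)

    assert mean_dfc("excitation") < -0.15
    assert mean_dfc("inhibition") > 0.05
    assert abs(mean_dfc("control")) < 0.1


def test_behavior_tracks_realized_fc_change():
    coh = generate_cohort(study_scenario(), seed=6)
    exc = [coh.behavior[a] for a in coh.animals if coh.groups[a] == "excitation"]
    inh = [coh.behavior[a] for a in coh.animals if coh.groups[a] == "inhibition"]
    ctl = [coh.behavior[a] for a in coh.animals if coh.groups[a] == "control"]
    assert np.mean(exc) > np.mean(ctl) > np.mean(inh)


def test_study_scenario_structure():
    cfg = study_scenario()
    cats = {r.category for r in cfg.rois}
    assert cats == {"seed", "thalamic-loop", "thalamic-nonloop", "cortical"}
    ranks = sorted(r.hierarchy_rank for r in cfg.rois if r.hierarchy_rank)
    assert ranks == list(range(1, 13))
    # cortical effect grows toward the unimodal end of the hierarchy
    dphi = cfg.delta_phi["excitation"]
    by_rank = [dphi[r.name] for r in sorted(
        (r for r in cfg.rois if r.category == "cortical"),
        key=lambda r: r.hierarchy_rank)]
    assert by_rank == sorted(by_rank)
    cfg.validate()
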