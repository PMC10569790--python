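import numpy as np
import pytest

from bolddyn.synthdata import RoiSpec, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)


def ar1(phi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Fast AR(1) simulation via the recursive filter."""
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -phi], rng.standard_normal(n))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-ROI null cohort shared across IO/pipeline tests."""
    cfg = SynthConfig(
        rois=(RoiSpec("roi_a", "thalamic-nonloop"), RoiSpec("roi_b", "thalamic-nonloop")),
        group_sizes={"control": 5, "excitation": 6},
        bandpass=False,
    )
    return generate_cohort(cfg, seed=77)
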