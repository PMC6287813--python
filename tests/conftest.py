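import numpy as np
import pytest

from kymokin import (
    GrowthSimConfig,
    LatticeSimConfig,
    ThresholdSettings,
    simulate_two_sided_kymograph,
)

# thresholds midway between the three noiseless intensity levels of the
# default lattice configuration (background 5, level step 10)
MID_THRESHOLDS = dict(low_threshold=10.0, high_threshold=20.0)


@pytest.fixture
def exact_settings():
    """Cleanup-free detection settings for noiseless kymographs."""
    return ThresholdSettings(
        **MID_THRESHOLDS, median_window=(1, 1), structuring_element=("disk", 0)
    )


@pytest.fixture
def robust_settings():
    """Default cleanup for noisy kymographs."""
    return ThresholdSettings(
        **MID_THRESHOLDS, median_window=(3, 3), structuring_element=("disk", 1)
    )


@pytest.fixture
def three_level_kymo():
    """Noiseless two-sided kymograph with nucleations on both sides, one
    same-side meeting, and a dissociation phase; plus its ground truth."""
    cfg = LatticeSimConfig(
        lattice_length=80,
        n_frames_assoc=120,
        n_frames_dissoc=120,
        elongation_rate=0.5,
        dissociation_end_rate=0.3,
        forced_nucleations=((0, 20, 5), (0, 60, 10), (1, 40, 30)),
        seed=7,
    )
    return simulate_two_sided_kymograph(cfg)


@pytest.fixture
def single_nucleation_kymo():
    cfg = LatticeSimConfig(
        lattice_length=60,
        n_frames_assoc=80,
        elongation_rate=1.0,
        forced_nucleations=((0, 30, 5),),
    )
    return simulate_two_sided_kymograph(cfg)
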