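import numpy as np
import pytest

from skinet import (BandSpec, ClassProfile, SOMMap, SyntheticConfig,
                    TrainingSchedule)


def make_map(width, height, P, K, seed=0, T=100, alpha0=0.5, sigma0=None,
             sigma_min=0.5, W=None, C=None):
    """Small map with an explicit, resolved schedule for unit tests."""
    sched = TrainingSchedule(T=T, alpha0=alpha0,
                             sigma0=sigma0 or max(width, height) / 2.0,
                             sigma_min=sigma_min)
    rng = np.random.default_rng(seed)
    if W is None:
        W = rng.random((width * height, P))
    if C is None:
        C = rng.random((width * height, K))
    return SOMMap(width, height, W, C, seed, sched)


@pytest.fixture
def separated_config():
    """Three classes with widely separated exclusive bands and mild noise —
    clusters a small map separates cleanly."""
    classes = (
        ClassProfile("a", exclusive=(BandSpec(700.0, width=12.0, amplitude=2.0),)),
        ClassProfile("b", exclusive=(BandSpec(1100.0, width=12.0, amplitude=2.0),)),
        ClassProfile("c", exclusive=(BandSpec(1500.0, width=12.0, amplitude=2.0),)),
    )
    return SyntheticConfig(classes=classes, n_channels=200, n_per_class=30,
                           noise_sd=0.05, baseline_scale=0.0, gain_sigma=0.0,
                           seed=11)
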