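import logging

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from zfecg import SimConfig, simulate_recording

# QRS-delineation collapse warnings are expected on noisy mutant traces
logging.getLogger("zfecg.detect").setLevel(logging.ERROR)
logging.getLogger("zfecg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def wt_noiseless():
    """Noiseless, wander-free wild-type recording with ground truth."""
    cfg = SimConfig.wildtype(seed=11, noise_sd_mV=0.0, wander_amp_mV=0.0)
    trace, truth = simulate_recording(cfg, "wt_clean", "WT")
    return trace, truth


@pytest.fixture(scope="session")
def wt_default():
    """Wild-type recording at default noise and wander."""
    cfg = SimConfig.wildtype(seed=3)
    trace, truth = simulate_recording(cfg, "wt_noisy", "WT")
    return trace, truth


@pytest.fixture(scope="session")
def class_ii_default():
    """Class II recording (suppressed QRS, doubled noise, frequent SA)."""
    cfg = SimConfig.class_ii(seed=5)
    trace, truth = simulate_recording(cfg, "c2", "ClassII")
    return trace, truth


def match_fraction(truth_times, det_times, tol_s=0.01):
    """Fraction of truth times recovered within tol_s."""
    truth_times = np.asarray(truth_times)
    det_times = np.asarray(det_times)
    if det_times.size == 0:
        return 0.0
    d = np.abs(truth_times[:, None] - det_times[None, :]).min(axis=1)
    return float((d < tol_s).mean())
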