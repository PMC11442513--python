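import numpy as np
import pytest

from bgosc import synth
from bgosc.io import assign_structures, derive_bipolar
from bgosc.preprocess import PreprocessConfig, condition, epoch
from bgosc.spectral import default_freq_grid, morlet_transform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_truth():
    return synth.GroundTruth(subject_id="sub-01", hemisphere="left", lf_peak_hz=8.5)


@pytest.fixture(scope="session")
def small_recording():
    """One hemisphere at reduced duration/rate for fast unit tests."""
    truth = synth.GroundTruth(subject_id="sub-01", hemisphere="left", lf_peak_hz=8.0)
    return synth.generate_hemisphere(truth, duration_s=60.0, fs=250.0, seed=7)


@pytest.fixture(scope="session")
def conditioned_pair(small_recording):
    """STR and GPi wavelet coefficients from the small recording."""
    retained = assign_structures(derive_bipolar(small_recording))
    cfg = PreprocessConfig()
    out = {}
    for structure in ("STR", "GPi"):
        y = condition(retained[structure].samples, small_recording.fs, cfg)
        ep = epoch(y, cfg.fs_out, cfg.epoch_length_s, structure=structure)
        out[structure] = morlet_transform(ep, default_freq_grid(2.0, 45.0))
    return out["STR"], out["GPi"]
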