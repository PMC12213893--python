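import numpy as np
import pytest

from wearval import synth
from wearval.types import DeviceModel


@pytest.fixture(scope="session")
def rr_steady_60():
    """60 s of perfectly regular beats at 60 bpm (1000 ms intervals)."""
    return synth.simulate_rr_series(60, 60, None, seed=1)


@pytest.fixture(scope="session")
def rr_variable():
    """120 s at 70 bpm with sinusoidal + jitter variability."""
    var = synth.RRVariability(lf_amp_ms=25, hf_amp_ms=35, jitter_sd_ms=8)
    return synth.simulate_rr_series(120, 70, var, seed=2)


@pytest.fixture(scope="session")
def ecg_clean_100(rr_steady_60):
    """Noiseless 100 Hz ECG of the steady beat train."""
    return synth.render_ecg(rr_steady_60, 100, DeviceModel(), duration_s=60, seed=0)


@pytest.fixture(scope="session")
def ecg_noisy_1000(rr_variable):
    """1000 Hz ECG with 5%-of-peak additive noise."""
    return synth.render_ecg(
        rr_variable, 1000, DeviceModel(noise_sd=0.05), duration_s=120, seed=3
    )


def beat_recovery(peak_times_s, truth_times_s, tol_s=0.02):
    """Fraction of ground-truth beats matched by a detected peak within tol."""
    truth = np.asarray(truth_times_s)
    pt = np.asarray(peak_times_s)
    if pt.size == 0:
        return 0.0
    d = np.abs(truth[:, None] - pt[None, :]).min(axis=1)
    return float((d < tol_s).mean())
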