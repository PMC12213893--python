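"""Cardiovascular processing: cleaning filters, peak detectors, parameters.

Implements the processing-configuration grid for ECG and PPG:

ECG cleaning
    ``nk_default``    high-pass 5th-order Butterworth, 0.5 Hz cutoff, plus
                      50 Hz powerline notch (applied only when fs > 100 Hz);
    ``langevin``      0.05 Hz high-pass (the cited source names a "notch"
                      at a single 0.05 Hz cutoff, which only defines a
                      high-pass — see docs/methods.md);
    ``elgendi_ecg``   8–20 Hz band-pass Butterworth (second-order sections);
    ``none``          identity.

PPG cleaning
    ``langevin_ppg``  0.7–3.5 Hz band-pass;
    ``elgendi_ppg``   3rd-order 0.5–8 Hz band-pass;
    ``nabian_ppg``    2nd-order 40 Hz low-pass (valid at fs = 100 Hz);
    ``none``          identity.

Peak detection
    ``brammer``         steepness of the absolute gradient marks QRS
                        regions, R peak = local maximum inside each region;
    ``elgendi_dual_ma`` dual moving averages of the squared signal with a
                        dynamic threshold (used for both ECG and PPG);
    ``nabian_window``   sliding-window local maxima;
    ``gamboa``          local maxima of the min–max-normalized signal
                        located via derivative zero crossings, gated on
                        candidate amplitude.

All filters are zero-phase (forward-backward) and length-preserving. All
detectors enforce a 250 ms refractory period (180 bpm plausibility bound)
by keeping the larger-amplitude peak of any too-close pair.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import CardioParams, PeakSeries, Recording

__all__ = [
    "ECG_CLEAN_METHODS",
    "PPG_CLEAN_METHODS",
    "ECG_PEAK_METHODS",
    "PPG_PEAK_METHODS",
    "compatibility_table",
    "clean_cardio",
    "detect_peaks",
    "peak_intervals",
    "cardio_parameters",
]

ECG_CLEAN_METHODS = ("nk_default", "langevin", "elgendi_ecg", "none")
PPG_CLEAN_METHODS = ("langevin_ppg", "elgendi_ppg", "nabian_ppg", "none")
ECG_PEAK_METHODS = ("brammer", "elgendi_dual_ma", "nabian_window", "gamboa")
PPG_PEAK_METHODS = ("elgendi_dual_ma",)

REFRACTORY_S = 0.25  # 180 bpm upper plausibility bound

# dual-moving-average parameters (event/beat window, threshold offset)
_ELGENDI_W_EVENT_S = 0.111
_ELGENDI_W_BEAT_S = 0.667
_ELGENDI_BETA = 0.08


def compatibility_table() -> dict:
    """Machine-readable grid of supported clean × peak combinations."""
    return {
        "ecg": {
            "clean": list(ECG_CLEAN_METHODS),
            "peaks": list(ECG_PEAK_METHODS),
            "pairs": [[c, p] for c in ECG_CLEAN_METHODS for p in ECG_PEAK_METHODS],
        },
        "ppg": {
            "clean": list(PPG_CLEAN_METHODS),
            "peaks": list(PPG_PEAK_METHODS),
            "pairs": [[c, p] for c in PPG_CLEAN_METHODS for p in PPG_PEAK_METHODS],
        },
    }


def _check_cutoff(method: str, fs_hz: float, *cutoffs: float) -> None:
    nyq = fs_hz / 2.0
    for c in cutoffs:
        if c >= nyq:
            raise ValueError(
                f"clean method {method!r}: cutoff {c} Hz >= Nyquist ({nyq} Hz) at fs={fs_hz} Hz"
            )


def clean_cardio(x: np.ndarray, fs_hz: float, method: str) -> np.ndarray:
    """Apply one of the named zero-phase cleaning filters; length preserved."""
    x = np.asarray(x, dtype=float)
    if method == "none":
        return x.copy()
    if method == "nk_default":
        _check_cutoff(method, fs_hz, 0.5)
        sos = sps.butter(5, 0.5, btype="highpass", fs=fs_hz, output="sos")
        y = sps.sosfiltfilt(sos, x)
        if fs_hz > 100:  # mains-region filtering only meaningful above ~100 Hz
            _check_cutoff(method, fs_hz, 50.0)
            b, a = sps.iirnotch(50.0, Q=30.0, fs=fs_hz)
            y = sps.filtfilt(b, a, y)
        return y
    if method == "langevin":
        _check_cutoff(method, fs_hz, 0.05)
        sos = sps.butter(5, 0.05, btype="highpass", fs=fs_hz, output="sos")
        return sps.sosfiltfilt(sos, x)
    if method == "elgendi_ecg":
        _check_cutoff(method, fs_hz, 8.0, 20.0)
        sos = sps.butter(3, [8.0, 20.0], btype="bandpass", fs=fs_hz, output="sos")
        return sps.sosfiltfilt(sos, x)
    if method == "langevin_ppg":
        _check_cutoff(method, fs_hz, 0.7, 3.5)
        sos = sps.butter(3, [0.7, 3.5], btype="bandpass", fs=fs_hz, output="sos")
        return sps.sosfiltfilt(sos, x)
    if method == "elgendi_ppg":
        _check_cutoff(method, fs_hz, 0.5, 8.0)
        sos = sps.butter(3, [0.5, 8.0], btype="bandpass", fs=fs_hz, output="sos")
        return sps.sosfiltfilt(sos, x)
    if method == "nabian_ppg":
        _check_cutoff(method, fs_hz, 40.0)
        sos = sps.butter(2, 40.0, btype="lowpass", fs=fs_hz, output="sos")
        return sps.sosfiltfilt(sos, x)
    raise ValueError(
        f"unknown clean method {method!r}; ECG: {ECG_CLEAN_METHODS}, PPG: {PPG_CLEAN_METHODS}"
    )


# ---------------------------------------------------------------------------
# peak detection


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(width, 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _apply_refractory(idx: np.ndarray, amps: np.ndarray, fs_hz: float) -> np.ndarray:
    """Greedily drop the smaller of any pair closer than the refractory period."""
    if idx.size < 2:
        return idx
    min_gap = int(round(REFRACTORY_S * fs_hz))
    keep: list[int] = []
    keep_amp: list[float] = []
    for i, a in zip(idx, amps):
        if keep and i - keep[-1] < min_gap:
            if a > keep_amp[-1]:
                keep[-1], keep_amp[-1] = int(i), float(a)
        else:
            keep.append(int(i))
            keep_amp.append(float(a))
    return np.asarray(keep, dtype=int)


def _peaks_brammer(x: np.ndarray, fs_hz: float) -> np.ndarray:
    # light pre-smoothing so sample-to-sample noise does not dominate the
    # gradient at high sampling rates; 20 ms barely blunts the QRS slope
    x = _moving_average(x, int(round(0.02 * fs_hz)))
    grad = np.abs(np.gradient(x))
    smooth = _moving_average(grad, int(round(0.10 * fs_hz)))
    p99 = np.percentile(smooth, 99)
    if p99 <= 0:
        return np.array([], dtype=int)
    thr = 0.4 * p99
    above = smooth > thr
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, x.size)
    idx = [lo + int(np.argmax(x[lo:hi])) for lo, hi in zip(starts, ends) if hi > lo]
    return np.asarray(idx, dtype=int)


def _peaks_elgendi(x: np.ndarray, fs_hz: float, modality: str = "ecg") -> np.ndarray:
    # The dual-MA method is defined on a band-passed squared signal
    # (8-20 Hz for QRS energy, 0.5-8 Hz for the pulse lobe); apply the band
    # here so block location does not depend on the upstream cleaning choice.
    band = (8.0, 20.0) if modality == "ecg" else (0.5, 8.0)
    if band[1] < fs_hz / 2:
        sos = sps.butter(3, band, btype="bandpass", fs=fs_hz, output="sos")
        xb = sps.sosfiltfilt(sos, x)
    else:
        xb = x
    y = np.clip(xb, 0, None) ** 2
    w1 = int(round(_ELGENDI_W_EVENT_S * fs_hz))
    w2 = int(round(_ELGENDI_W_BEAT_S * fs_hz))
    ma_event = _moving_average(y, w1)
    ma_beat = _moving_average(y, w2)
    thr = ma_beat + _ELGENDI_BETA * float(np.mean(y))
    above = ma_event > thr
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        starts = np.insert(starts, 0, 0)
    if above.size and above[-1]:
        ends = np.append(ends, x.size)
    idx = [
        lo + int(np.argmax(x[lo:hi]))
        for lo, hi in zip(starts, ends)
        if hi - lo >= w1  # blocks shorter than the event window are noise
    ]
    return np.asarray(idx, dtype=int)


def _peaks_nabian(x: np.ndarray, fs_hz: float) -> np.ndarray:
    # window = 2 x the shortest plausible beat interval (180 bpm)
    half = int(round(60.0 / 180.0 * fs_hz))
    med = np.median(x)
    spread = np.percentile(x, 99) - med
    if spread <= 0:
        return np.array([], dtype=int)
    gate = med + 0.5 * spread
    idx, _ = sps.find_peaks(x, height=gate)
    keep = [
        i
        for i in idx
        if x[i] >= x[max(i - half, 0):min(i + half + 1, x.size)].max()
    ]
    return np.asarray(keep, dtype=int)


def _peaks_gamboa(x: np.ndarray, fs_hz: float) -> np.ndarray:
    rng_x = x.max() - x.min()
    if rng_x <= 0:
        return np.array([], dtype=int)
    norm = (x - x.min()) / rng_x
    # local maxima (negative second derivative at a falling first-derivative
    # zero crossing); a small prominence floor discards numeric ripple in
    # flat baseline stretches before the amplitude gate is formed
    cross, _ = sps.find_peaks(norm, prominence=0.05)
    if cross.size == 0:
        return cross
    amps = norm[cross]
    gate = 0.8 * np.percentile(amps, 80)
    return cross[amps >= gate]


_DETECTORS = {
    "brammer": _peaks_brammer,
    "elgendi_dual_ma": _peaks_elgendi,
    "nabian_window": _peaks_nabian,
    "gamboa": _peaks_gamboa,
}


def detect_peaks(
    x: np.ndarray,
    fs_hz: float,
    method: str,
    modality: str = "ecg",
    t0_s: float = 0.0,
) -> PeakSeries:
    """Detect beat/pulse peaks; returns strictly increasing times (s).

    A flat or empty signal yields an empty PeakSeries rather than an
    error. ``t0_s`` offsets the returned times (absolute-clock peaks when
    called with a recording's start time).
    """
    if method not in _DETECTORS:
        raise ValueError(f"unknown peak method {method!r}; have {sorted(_DETECTORS)}")
    x = np.asarray(x, dtype=float)
    if x.size < int(2 * fs_hz):
        raise ValueError("need at least 2 s of signal for peak detection")
    if np.ptp(x) == 0:
        return PeakSeries(np.array([]), modality=modality, fs_hz=fs_hz)
    if method == "elgendi_dual_ma":
        idx = _peaks_elgendi(x, fs_hz, modality)
    else:
        idx = _DETECTORS[method](x, fs_hz)
    idx = np.unique(idx)
    idx = _apply_refractory(idx, x[idx], fs_hz)
    return PeakSeries(t0_s + idx / fs_hz, modality=modality, fs_hz=fs_hz)


def detect_peaks_recording(
    rec: Recording, method: str, channel: int = 0, modality: str | None = None
) -> PeakSeries:
    """Convenience wrapper: detect peaks on one channel of a Recording."""
    modality = modality or rec.meta.get("modality", "ecg")
    if modality not in ("ecg", "ppg"):
        modality = "ecg"
    return detect_peaks(
        rec.data[channel], rec.fs_hz, method, modality=modality, t0_s=rec.t_start_s
    )


# ---------------------------------------------------------------------------
# parameters


def peak_intervals(peaks: PeakSeries) -> np.ndarray:
    """Beat-to-beat intervals in ms (length = n_peaks - 1)."""
    if peaks.n_peaks < 2:
        raise ValueError(f"insufficient peaks: need >= 2, got {peaks.n_peaks}")
    return np.diff(peaks.peak_times_s) * 1000.0


def cardio_parameters(intervals_ms: np.ndarray) -> CardioParams:
    """Mean HR, interval SD (SDNN) and RMSSD from beat intervals.

    ``mean_hr_bpm = 60000/mean``; SD is the sample SD (ddof=1); RMSSD is
    the root mean square of successive differences. Parameters that cannot
    be computed from too few intervals are NaN.
    """
    iv = np.asarray(intervals_ms, dtype=float)
    n = iv.size
    hr = 60000.0 / float(np.mean(iv)) if n >= 1 else float("nan")
    sd = float(np.std(iv, ddof=1)) if n >= 2 else float("nan")
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2))) if n >= 2 else float("nan")
    return CardioParams(mean_hr_bpm=hr, sd_intervals_ms=sd, rmssd_ms=rmssd, n_intervals=n)
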