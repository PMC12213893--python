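"""Electrodermal activity: cleaning, tonic/phasic split, SCR detection.

Pipeline grid (stable string ids used in configs and reports):

cleaning       ``nk3hz`` (4th-order Butterworth low-pass, 3 Hz),
               ``biosppy5hz`` (same, 5 Hz), ``none``;
decomposition  ``highpass005`` — 4th-order 0.05 Hz high-pass gives the
               phasic component, tonic = signal − phasic;
               ``median4s`` — tonic = 4-s rolling median (reflect-padded),
               phasic = signal − tonic;
               ``cvx`` — sparse-driver convex deconvolution; requires a
               quadratic-program solver and raises NotImplementedError
               when none is available (never a silent fallback);
SCR detection  ``nk_default`` — first-derivative maxima over a dynamic
               threshold, validated by SCR rise-time shape;
               ``kim`` — phasic smoothed with a 20-point Bartlett window,
               SCRs between consecutive −/+ and +/− zero crossings;
               ``gamboa`` — second-derivative-located peak/onset pairing;
               ``nabian`` — derivative zero-crossing pairs, rejecting
               amplitudes below 10% of the maximum detected amplitude.

Both subtractive decompositions conserve the input exactly:
tonic + phasic = cleaned signal to machine precision.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .types import EdaDecomposition, EdaParams, ScrEvent

__all__ = [
    "EDA_CLEAN_METHODS",
    "EDA_DECOMP_METHODS",
    "EDA_PEAK_METHODS",
    "clean_eda",
    "decompose_eda",
    "detect_scrs",
    "eda_parameters",
    "PlausibilityVerdict",
    "screen_pipeline_plausibility",
]

EDA_CLEAN_METHODS = ("nk3hz", "biosppy5hz", "none")
EDA_DECOMP_METHODS = ("highpass005", "median4s", "cvx")
EDA_PEAK_METHODS = ("nk_default", "kim", "gamboa", "nabian")

#: SCR-rate screen: mean > 30/min across runs implies overestimation.
MAX_PLAUSIBLE_SCR_PER_MIN = 30.0
#: "close to zero" mean amplitude cutoff for pipeline exclusion (μS).
EPSILON_AMP_US = 0.01

_MIN_EVENT_AMP_US = 1e-4  # numeric-ripple floor for candidate segments


def clean_eda(x: np.ndarray, fs_hz: float, method: str) -> np.ndarray:
    """Low-pass smooth an EDA signal (zero-phase, length preserved)."""
    x = np.asarray(x, dtype=float)
    if method == "none":
        return x.copy()
    cutoffs = {"nk3hz": 3.0, "biosppy5hz": 5.0}
    if method not in cutoffs:
        raise ValueError(f"unknown EDA clean method {method!r}; have {EDA_CLEAN_METHODS}")
    cut = cutoffs[method]
    if cut >= fs_hz / 2:
        raise ValueError(
            f"clean method {method!r}: cutoff {cut} Hz >= Nyquist at fs={fs_hz} Hz"
        )
    sos = sps.butter(4, cut, btype="lowpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def decompose_eda(x: np.ndarray, fs_hz: float, method: str) -> EdaDecomposition:
    """Split skin conductance into tonic (SCL) and phasic (SCR) components."""
    x = np.asarray(x, dtype=float)
    if method == "highpass005":
        if 0.05 >= fs_hz / 2:
            raise ValueError(f"highpass005 needs fs > 0.1 Hz, got {fs_hz}")
        sos = sps.butter(4, 0.05, btype="highpass", fs=fs_hz, output="sos")
        phasic = sps.sosfiltfilt(sos, x)
        tonic = x - phasic
    elif method == "median4s":
        if x.size < int(8 * fs_hz):
            raise ValueError("median4s needs at least 8 s of data")
        win = int(round(4.0 * fs_hz))
        win += 1 - win % 2
        tonic = ndimage.median_filter(x, size=win, mode="reflect")
        phasic = x - tonic
    elif method == "cvx":
        raise NotImplementedError(
            "cvx decomposition requires a quadratic-program solver (cvxopt/osqp), "
            "which is not installed; use 'highpass005' or 'median4s'"
        )
    else:
        raise ValueError(f"unknown decomposition {method!r}; have {EDA_DECOMP_METHODS}")
    return EdaDecomposition(tonic=tonic, phasic=phasic, method=method, fs_hz=fs_hz)


# ---------------------------------------------------------------------------
# SCR detection


def _zero_cross_pairs(d: np.ndarray) -> list[tuple[int, int]]:
    """(rising, falling) zero-crossing index pairs of a derivative-like series."""
    sign = np.sign(d)
    rising = np.flatnonzero((sign[:-1] <= 0) & (sign[1:] > 0)) + 1
    falling = np.flatnonzero((sign[:-1] > 0) & (sign[1:] <= 0)) + 1
    pairs = []
    for r in rising:
        f = falling[falling > r]
        # a rise with no later fall closes at the signal end (slow decay)
        pairs.append((int(r), int(f[0]) if f.size else d.size - 1))
    return pairs


def _scrs_nk_default(phasic: np.ndarray, fs_hz: float) -> list[ScrEvent]:
    d = np.gradient(phasic) * fs_hz
    if d.max() <= 0:
        return []
    # dynamic threshold: 10% of the tallest interior derivative maximum
    # (a 2-s edge margin keeps zero-phase filter transients out of both
    # the threshold and the candidate set)
    didx_all, props = sps.find_peaks(d, height=0)
    margin = int(2 * fs_hz)
    interior = (didx_all >= margin) & (didx_all <= d.size - margin)
    didx_all, heights = didx_all[interior], props["peak_heights"][interior]
    if didx_all.size == 0:
        return []
    thr = 0.1 * heights.max()
    didx = didx_all[heights >= thr]
    # prominence floor makes peak/onset location robust to sample noise
    peaks_p, _ = sps.find_peaks(phasic, prominence=0.01)
    sign = np.sign(np.gradient(phasic))
    minima = np.flatnonzero((sign[:-1] <= 0) & (sign[1:] > 0)) + 1
    minima = np.concatenate(([0], minima))
    events = []
    for i in didx:
        later = peaks_p[peaks_p >= i]
        prior = minima[minima <= i]
        if later.size == 0 or prior.size == 0:
            continue
        j, k = int(later[0]), int(prior[-1])
        rise_s = (j - k) / fs_hz
        amp = phasic[j] - phasic[k]
        if 0.5 <= rise_s <= 5.0 and amp > _MIN_EVENT_AMP_US and k < j:
            events.append(ScrEvent(onset_s=k / fs_hz, peak_s=j / fs_hz, amplitude_uS=float(amp)))
    return _dedupe(events)


def _scrs_kim(phasic: np.ndarray, fs_hz: float) -> list[ScrEvent]:
    win = np.bartlett(20)
    smooth = np.convolve(phasic, win / win.sum(), mode="same")
    events = []
    for r, f in _zero_cross_pairs(smooth):
        seg = phasic[r:f]
        if seg.size == 0:
            continue
        j = r + int(np.argmax(seg))
        amp = float(phasic[j] - phasic[r])
        if amp > _MIN_EVENT_AMP_US and j > r:
            events.append(ScrEvent(onset_s=r / fs_hz, peak_s=j / fs_hz, amplitude_uS=amp))
    return _dedupe(events)


def _scrs_gamboa(phasic: np.ndarray, fs_hz: float) -> list[ScrEvent]:
    peaks, _ = sps.find_peaks(phasic)
    d = np.gradient(phasic)
    sign = np.sign(d)
    # weak minima: derivative turns positive (handles flat-zero baselines)
    minima = np.flatnonzero((sign[:-1] <= 0) & (sign[1:] > 0)) + 1
    minima = np.concatenate(([0], minima))  # signal start can serve as an onset
    events = []
    max_pair_s = 5.0
    for p in peaks:
        prior = minima[(minima < p) & (minima >= p - max_pair_s * fs_hz)]
        if prior.size == 0:
            continue  # unpaired peak dropped
        o = int(prior[-1])
        amp = float(phasic[p] - phasic[o])
        if amp > _MIN_EVENT_AMP_US:
            events.append(ScrEvent(onset_s=o / fs_hz, peak_s=p / fs_hz, amplitude_uS=amp))
    return _dedupe(events)


def _scrs_nabian(phasic: np.ndarray, fs_hz: float) -> list[ScrEvent]:
    d = np.gradient(phasic)
    candidates = []
    for r, f in _zero_cross_pairs(d):
        # r: derivative turns positive (onset/local min); f: turns negative (peak)
        seg = phasic[r:f + 1]
        if seg.size == 0:
            continue
        j = r + int(np.argmax(seg))
        amp = float(phasic[j] - phasic[r])
        if amp > _MIN_EVENT_AMP_US and j > r:
            candidates.append(ScrEvent(onset_s=r / fs_hz, peak_s=j / fs_hz, amplitude_uS=amp))
    if not candidates:
        return []
    max_amp = max(e.amplitude_uS for e in candidates)
    kept = [e for e in candidates if e.amplitude_uS >= 0.10 * max_amp]
    return _dedupe(kept)


def _dedupe(events: list[ScrEvent]) -> list[ScrEvent]:
    """Time-order events and collapse duplicates sharing a peak sample."""
    out: dict[float, ScrEvent] = {}
    for e in sorted(events, key=lambda e: e.peak_s):
        if e.peak_s not in out or e.amplitude_uS > out[e.peak_s].amplitude_uS:
            out[e.peak_s] = e
    return list(out.values())


_SCR_DETECTORS = {
    "nk_default": _scrs_nk_default,
    "kim": _scrs_kim,
    "gamboa": _scrs_gamboa,
    "nabian": _scrs_nabian,
}


def detect_scrs(phasic: np.ndarray, fs_hz: float, method: str) -> list[ScrEvent]:
    """Detect skin conductance responses in a phasic series.

    Returns time-ordered events with each method's own amplitude
    definition; an all-zero phasic series yields an empty list.
    """
    if method not in _SCR_DETECTORS:
        raise ValueError(f"unknown SCR method {method!r}; have {sorted(_SCR_DETECTORS)}")
    phasic = np.asarray(phasic, dtype=float)
    if phasic.size < 3 or np.ptp(phasic) == 0:
        return []
    return _SCR_DETECTORS[method](phasic, fs_hz)


# ---------------------------------------------------------------------------
# parameters and plausibility screen


def eda_parameters(
    decomp: EdaDecomposition, events: list[ScrEvent], duration_s: float
) -> EdaParams:
    """Run-level EDA parameters: SCL mean/SD, SCR rate and mean amplitude."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    amps = [e.amplitude_uS for e in events]
    return EdaParams(
        scl_mean_uS=float(np.mean(decomp.tonic)),
        scl_sd_uS=float(np.std(decomp.tonic, ddof=1)) if decomp.tonic.size > 1 else 0.0,
        scr_per_min=len(events) / (duration_s / 60.0),
        scr_amp_mean_uS=float(np.mean(amps)) if amps else float("nan"),
        duration_min=duration_s / 60.0,
    )


class PlausibilityVerdict:
    """Keep/exclude decision for one EDA pipeline across runs."""

    def __init__(self, excluded: bool, reason: str, mean_rate: float, mean_amp: float):
        self.excluded = excluded
        self.reason = reason
        self.mean_scr_per_min = mean_rate
        self.mean_amplitude_uS = mean_amp

    def __repr__(self) -> str:
        state = "excluded" if self.excluded else "retained"
        return f"PlausibilityVerdict({state}: {self.reason})"

    def to_dict(self) -> dict:
        return {
            "excluded": self.excluded,
            "reason": self.reason,
            "mean_scr_per_min": self.mean_scr_per_min,
            "mean_amplitude_uS": self.mean_amplitude_uS,
        }


def screen_pipeline_plausibility(
    per_run_params: list[EdaParams],
    max_rate_per_min: float = MAX_PLAUSIBLE_SCR_PER_MIN,
    epsilon_amp_uS: float = EPSILON_AMP_US,
) -> PlausibilityVerdict:
    """Screen a pipeline on reference-device SCR statistics across runs.

    Excluded when the across-run mean SCR rate exceeds 30/min (gross
    overestimation — plausible rates are 1–3/min at rest, up to ~25/min
    under high arousal) or when the mean detected amplitude is empty or
    close to zero (< 0.01 μS).
    """
    if not per_run_params:
        raise ValueError("need at least one run to screen a pipeline")
    mean_rate = float(np.mean([p.scr_per_min for p in per_run_params]))
    amps = [p.scr_amp_mean_uS for p in per_run_params if not np.isnan(p.scr_amp_mean_uS)]
    mean_amp = float(np.mean(amps)) if amps else 0.0
    if mean_rate > max_rate_per_min:
        return PlausibilityVerdict(
            True, f"SCR overestimation: mean {mean_rate:.1f}/min > {max_rate_per_min}/min",
            mean_rate, mean_amp,
        )
    if mean_amp < epsilon_amp_uS:
        return PlausibilityVerdict(
            True, f"near-zero amplitudes: mean {mean_amp:.4f} μS < {epsilon_amp_uS} μS",
            mean_rate, mean_amp,
        )
    return PlausibilityVerdict(False, "plausible", mean_rate, mean_amp)
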