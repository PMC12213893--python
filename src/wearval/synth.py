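"""Synthetic paired-device recordings with known ground truth.

Emulates the study setting end to end: a shared cardiac beat train is
rendered both as a reference ECG (1000 Hz by convention) and as three PPG
wavelength streams on a slower wearable (100 Hz); a shared electrodermal
ground truth (tonic level + Bateman-shaped SCRs) is rendered through two
devices with differing gain/offset/noise to mimic palm vs. upper-arm
placement. Every render stores its ground truth (beat times, SCR events)
in ``Recording.meta`` so downstream stages can be tested without real data.

Morphology is deliberately stylized: the ECG template is a biphasic QRS
spike plus a smaller T wave, the PPG pulse a skewed gamma-like lobe —
enough structure for every supported cleaning filter and peak detector,
with no claim of biophysical realism.

All randomness flows from one explicit integer seed per call; there is no
global random state.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import DeviceModel, Recording, RRSeries, ScrShape

__all__ = [
    "RRVariability",
    "simulate_rr_series",
    "render_ecg",
    "render_ppg",
    "render_eda_pair",
    "bateman_kernel",
    "Flatline",
    "BurstNoise",
    "BeatDeletion",
    "inject_artifacts",
]

#: Default transit delay from R peak to peripheral pulse peak (s);
#: physiologic pulse-transit order of magnitude.
DEFAULT_PULSE_DELAY_S = 0.2

_MIN_INTERVAL_MS = 250.0  # hard floor keeping generated intervals physiologic


@dataclass(frozen=True)
class RRVariability:
    """Beat-interval variability model: two sinusoids plus white jitter.

    The interval sequence is ``base + lf·sin(2π·f_lf·t) +
    hf·sin(2π·f_hf·t) + ε`` with ``ε ~ N(0, jitter_sd_ms²)``. The HF term
    (~0.25 Hz) mimics respiratory sinus arrhythmia, the LF term (~0.1 Hz)
    baroreflex-band variability; amplitudes are in ms so SDNN/RMSSD targets
    have closed forms.
    """

    lf_amp_ms: float = 0.0
    hf_amp_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25

    def is_zero(self) -> bool:
        return self.lf_amp_ms == 0 and self.hf_amp_ms == 0 and self.jitter_sd_ms == 0


def simulate_rr_series(
    duration_s: float,
    base_hr_bpm: float,
    variability: RRVariability | None = None,
    seed: int | None = None,
) -> RRSeries:
    """Generate a beat train covering ``[0, duration_s]``.

    The first beat is at t=0; beats are emitted while the next beat time
    stays within the duration. With zero variability the intervals are
    exactly ``60000/base_hr_bpm`` ms.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if not 30.0 <= base_hr_bpm <= 180.0:
        raise ValueError(f"base_hr_bpm must be in [30, 180], got {base_hr_bpm}")
    var = variability or RRVariability()
    rng = np.random.default_rng(seed)
    base_ms = 60000.0 / base_hr_bpm

    intervals: list[float] = []
    t = 0.0
    eps = 1e-9
    while True:
        iv = base_ms
        if not var.is_zero():
            iv += var.lf_amp_ms * np.sin(2 * np.pi * var.lf_freq_hz * t)
            iv += var.hf_amp_ms * np.sin(2 * np.pi * var.hf_freq_hz * t)
            if var.jitter_sd_ms > 0:
                iv += rng.normal(0.0, var.jitter_sd_ms)
        iv = max(iv, _MIN_INTERVAL_MS)
        if t + iv / 1000.0 > duration_s + eps:
            break
        intervals.append(iv)
        t += iv / 1000.0
    if not intervals:
        raise ValueError("duration too short to contain a single beat interval")
    return RRSeries(interval_ms=np.asarray(intervals), t0_s=0.0)


# ---------------------------------------------------------------------------
# waveform templates


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _ecg_waveform(t: np.ndarray, beat_times: np.ndarray) -> np.ndarray:
    """Stylized QRS (biphasic narrow spike) + smaller T wave per beat."""
    y = np.zeros_like(t)
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    half = int(0.6 * fs)  # template support: [-0.1, +0.5] s around the R peak
    for tb in beat_times:
        c = int(round((tb - t[0]) * fs))
        lo, hi = max(c - half, 0), min(c + half, t.size)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        y[lo:hi] += (
            1.0 * _gauss(tt, tb, 0.012)
            - 0.15 * _gauss(tt, tb - 0.028, 0.010)
            - 0.25 * _gauss(tt, tb + 0.028, 0.010)
            + 0.35 * _gauss(tt, tb + 0.30, 0.055)
        )
    return y


_PPG_ALPHA = 3.0  # gamma shape; peak at (alpha-1)*theta after lobe onset
_PPG_THETA = 0.125


def _ppg_waveform(t: np.ndarray, pulse_peak_times: np.ndarray) -> np.ndarray:
    """Skewed gamma-like pulse lobe, peak-normalized, peak at the given times."""
    y = np.zeros_like(t)
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    t_peak = (_PPG_ALPHA - 1.0) * _PPG_THETA  # 0.25 s after lobe onset
    support = int(1.4 * fs)
    peak_val = (t_peak / _PPG_THETA) ** (_PPG_ALPHA - 1) * np.exp(-t_peak / _PPG_THETA)
    for tp in pulse_peak_times:
        onset = tp - t_peak
        c = int(round((onset - t[0]) * fs))
        lo, hi = max(c, 0), min(c + support, t.size)
        if lo >= hi:
            continue
        v = t[lo:hi] - onset
        v = np.where(v > 0, v, 0.0)
        y[lo:hi] += (v / _PPG_THETA) ** (_PPG_ALPHA - 1) * np.exp(-v / _PPG_THETA) / peak_val
    return y


def _apply_device(
    clean: np.ndarray, t: np.ndarray, device: DeviceModel, rng: np.random.Generator
) -> np.ndarray:
    y = device.gain * clean + device.offset
    if device.drift_amp:
        phase = rng.uniform(0, 2 * np.pi)
        y = y + device.drift_amp * np.sin(2 * np.pi * device.drift_freq_hz * t + phase)
    if device.noise_sd:
        y = y + rng.normal(0.0, device.noise_sd, size=y.shape)
    return y


def render_ecg(
    rr: RRSeries,
    fs_hz: float,
    device: DeviceModel | None = None,
    duration_s: float | None = None,
    seed: int | None = None,
) -> Recording:
    """Render an ECG recording from a beat train.

    One R-shaped template is placed per beat, centered at
    ``beat time + device.lag_s``; the ground-truth beat times are stored in
    ``meta["beat_times_s"]``. Beats whose shifted time falls outside the
    rendered duration are truncated with a warning.
    """
    if fs_hz < 100:
        raise ValueError(f"ECG rendering requires fs_hz >= 100, got {fs_hz}")
    device = device or DeviceModel()
    rng = np.random.default_rng(seed)
    beats = rr.beat_times_s() + device.lag_s
    if duration_s is None:
        duration_s = float(beats[-1]) + 1.0
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    inside = (beats >= 0) & (beats < duration_s)
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} beats fall outside the rendered duration; truncated",
            stacklevel=2,
        )
    beats = beats[inside]
    clean = _ecg_waveform(t, beats)
    y = _apply_device(clean, t, device, rng)
    return Recording(
        data=y[np.newaxis, :],
        fs_hz=fs_hz,
        t_start_s=0.0,
        channel_labels=["ecg"],
        device_id="reference_ecg",
        meta={"modality": "ecg", "beat_times_s": beats.tolist()},
    )


def render_ppg(
    rr: RRSeries,
    fs_hz: float,
    devices: Sequence[DeviceModel] | None = None,
    pulse_delay_s: float = DEFAULT_PULSE_DELAY_S,
    duration_s: float | None = None,
    seed: int | None = None,
) -> Recording:
    """Render three PPG wavelength streams (green/red/infrared).

    All streams share the pulse timing ``beat + pulse_delay_s`` (plus each
    stream's own ``lag_s``); gain, drift and noise are independent per
    stream. Exactly three device models are required.
    """
    if fs_hz < 25:
        raise ValueError(f"PPG rendering requires fs_hz >= 25, got {fs_hz}")
    if devices is None:
        devices = (DeviceModel(), DeviceModel(), DeviceModel())
    if len(devices) != 3:
        raise ValueError(f"render_ppg needs exactly 3 device models, got {len(devices)}")
    rng = np.random.default_rng(seed)
    pulse_times = rr.beat_times_s() + pulse_delay_s
    if duration_s is None:
        duration_s = float(pulse_times[-1]) + max(d.lag_s for d in devices) + 1.0
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    channels = []
    for dev in devices:
        clean = _ppg_waveform(t, pulse_times + dev.lag_s)
        channels.append(_apply_device(clean, t, dev, rng))
    return Recording(
        data=np.vstack(channels),
        fs_hz=fs_hz,
        t_start_s=0.0,
        channel_labels=["ppg_green", "ppg_red", "ppg_ir"],
        device_id="wearable_ppg",
        meta={
            "modality": "ppg",
            "beat_times_s": rr.beat_times_s().tolist(),
            "pulse_delay_s": pulse_delay_s,
            "pulse_peak_times_s": pulse_times.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# electrodermal activity


def bateman_kernel(t: np.ndarray, shape: ScrShape) -> np.ndarray:
    """Peak-normalized Bateman kernel: ``exp(-t/τd) - exp(-t/τr)`` for t ≥ 0.

    Normalized so the maximum equals ``shape.amplitude_uS``, making the
    configured amplitude the literal SCR amplitude.
    """
    tr, td = shape.tau_rise_s, shape.tau_decay_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / td) - np.exp(-np.clip(t, 0, None) / tr), 0.0)
    return shape.amplitude_uS * out / peak


def _eda_ground_truth(
    t: np.ndarray,
    tonic_level_uS: float,
    tonic_slope_uS_per_s: float,
    scr_events: Sequence[tuple[float, ScrShape]],
) -> tuple[np.ndarray, np.ndarray]:
    tonic = tonic_level_uS + tonic_slope_uS_per_s * t
    phasic = np.zeros_like(t)
    for t_ev, shape in scr_events:
        phasic += bateman_kernel(t - t_ev, shape)
    return tonic, phasic


def render_eda_pair(
    duration_s: float,
    fs_a: float,
    fs_b: float,
    tonic_level_uS: float = 5.0,
    tonic_slope_uS_per_s: float = 0.0,
    scr_events: Sequence[tuple[float, ScrShape]] = (),
    device_a: DeviceModel | None = None,
    device_b: DeviceModel | None = None,
    seed: int | None = None,
) -> tuple[Recording, Recording]:
    """Render the same electrodermal ground truth through two devices.

    Ground truth = linear tonic drift + superposed peak-normalized Bateman
    SCRs (overlap allowed). Each device samples the shared continuous-time
    truth at its own rate, shifted by its lag and passed through its
    gain/offset/drift/noise model — emulating palm vs. upper-arm placement.
    Negative total conductance is clipped at 0 with a warning. The event
    list is stored in both recordings' metadata.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    for t_ev, _ in scr_events:
        if not 0 <= t_ev <= duration_s:
            raise ValueError(f"SCR event at {t_ev}s outside [0, {duration_s}]s")
    device_a = device_a or DeviceModel()
    device_b = device_b or DeviceModel()
    rng = np.random.default_rng(seed)

    truth_meta = {
        "modality": "eda",
        "tonic_level_uS": tonic_level_uS,
        "tonic_slope_uS_per_s": tonic_slope_uS_per_s,
        "scr_events": [
            {
                "time_s": float(t_ev),
                "amplitude_uS": s.amplitude_uS,
                "tau_rise_s": s.tau_rise_s,
                "tau_decay_s": s.tau_decay_s,
            }
            for t_ev, s in scr_events
        ],
    }

    recs = []
    for fs, dev, dev_id in ((fs_a, device_a, "eda_a"), (fs_b, device_b, "eda_b")):
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        tonic, phasic = _eda_ground_truth(
            t - dev.lag_s, tonic_level_uS, tonic_slope_uS_per_s, scr_events
        )
        y = _apply_device(tonic + phasic, t, dev, rng)
        if (y < 0).any():
            warnings.warn("negative conductance clipped at 0 μS", stacklevel=2)
            y = np.clip(y, 0.0, None)
        recs.append(
            Recording(
                data=y[np.newaxis, :],
                fs_hz=fs,
                channel_labels=["eda"],
                device_id=dev_id,
                meta=dict(truth_meta),
            )
        )
    return recs[0], recs[1]


# ---------------------------------------------------------------------------
# artifact injection


@dataclass(frozen=True)
class Flatline:
    """Dropout: the window is held at its first sample's value."""

    t_begin_s: float
    t_end_s: float


@dataclass(frozen=True)
class BurstNoise:
    """Additive white noise over a window."""

    t_begin_s: float
    t_end_s: float
    noise_sd: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class BeatDeletion:
    """Erase rendered beats in a window by linear interpolation across them.

    Requires ground-truth beat (or pulse-peak) times in ``Recording.meta``;
    produces the peak gaps the quality rules must reject.
    """

    t_begin_s: float
    t_end_s: float
    half_width_s: float = 0.35


Artifact = Flatline | BurstNoise | BeatDeletion


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def inject_artifacts(rec: Recording, artifacts: Sequence[Artifact]) -> Recording:
    """Return a copy of ``rec`` with the requested artifacts applied.

    Overlapping windows of the same artifact kind are merged; samples
    outside artifact windows are bit-identical to the input. An empty
    artifact list returns an identical copy.
    """
    out = rec.copy()
    if not artifacts:
        return out
    rel_t0 = out.t_start_s
    for a in artifacts:
        if a.t_begin_s >= a.t_end_s:
            raise ValueError(f"artifact window [{a.t_begin_s}, {a.t_end_s}] is empty")
        if a.t_begin_s < rel_t0 or a.t_end_s > out.t_end_s:
            raise ValueError("artifact window outside the recording")

    def idx(ts: float) -> int:
        return int(round((ts - rel_t0) * out.fs_hz))

    flats = _merge_windows(
        [(a.t_begin_s, a.t_end_s) for a in artifacts if isinstance(a, Flatline)]
    )
    for lo, hi in flats:
        i0, i1 = idx(lo), idx(hi)
        out.data[:, i0:i1] = out.data[:, i0:i0 + 1]

    for a in artifacts:
        if isinstance(a, BurstNoise):
            i0, i1 = idx(a.t_begin_s), idx(a.t_end_s)
            rng = np.random.default_rng(a.seed)
            out.data[:, i0:i1] += rng.normal(0.0, a.noise_sd, size=(out.n_channels, i1 - i0))
        elif isinstance(a, BeatDeletion):
            beat_key = "pulse_peak_times_s" if "pulse_peak_times_s" in out.meta else "beat_times_s"
            beats = np.asarray(out.meta.get(beat_key, []), dtype=float)
            if beats.size == 0:
                raise ValueError("BeatDeletion requires ground-truth beat times in meta")
            sel = beats[(beats >= a.t_begin_s) & (beats < a.t_end_s)]
            windows = _merge_windows(
                [(tb - a.half_width_s, tb + a.half_width_s) for tb in sel]
            )
            for lo, hi in windows:
                i0 = max(idx(lo), 0)
                i1 = min(idx(hi), out.n_samples - 1)
                if i1 <= i0:
                    continue
                for ch in range(out.n_channels):
                    out.data[ch, i0:i1 + 1] = np.linspace(
                        out.data[ch, i0], out.data[ch, i1], i1 - i0 + 1
                    )
    return out
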