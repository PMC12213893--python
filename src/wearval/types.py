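"""Core containers shared across the pipeline.

All time is expressed in seconds on a single shared clock (the two devices
are assumed to have been synchronized at acquisition time); beat-to-beat
intervals are in milliseconds and skin conductance in microsiemens.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "RunSegment",
    "RRSeries",
    "DeviceModel",
    "ScrShape",
    "PeakSeries",
    "CardioParams",
    "ScrEvent",
    "EdaDecomposition",
    "EdaParams",
    "QualityThresholds",
]


@dataclass
class Recording:
    """Uniformly sampled multi-channel time series from one device.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample values, one row per channel.
    fs_hz : float
        Sampling rate shared by all channels in the recording.
    t_start_s : float
        Absolute start time on the shared clock.
    channel_labels : list of str
        One label per channel (e.g. ``["ecg"]`` or ``["ppg_green",
        "ppg_red", "ppg_ir"]``).
    device_id : str
        Free-form device identifier.
    meta : dict
        Free-form metadata; the synthetic generator stores ground truth
        (beat times, SCR events) here and the loaders round-trip it via a
        JSON sidecar.
    """

    data: np.ndarray
    fs_hz: float
    t_start_s: float = 0.0
    channel_labels: list[str] = field(default_factory=list)
    device_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if np.isnan(self.data).any():
            raise ValueError("Recording contains NaN samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n_samples) / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        import copy as _copy

        return Recording(
            data=self.data.copy(),
            fs_hz=self.fs_hz,
            t_start_s=self.t_start_s,
            channel_labels=list(self.channel_labels),
            device_id=self.device_id,
            meta=_copy.deepcopy(self.meta),
        )


@dataclass(frozen=True)
class RunSegment:
    """A labeled segment (experimental condition) on the shared clock."""

    condition: str
    t_begin_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if not self.t_begin_s < self.t_end_s:
            raise ValueError(
                f"segment bounds must satisfy t_begin < t_end, got "
                f"[{self.t_begin_s}, {self.t_end_s}]"
            )


@dataclass
class RRSeries:
    """Ground-truth beat-to-beat intervals.

    ``interval_ms[i]`` is the time between beats ``i`` and ``i+1``; the
    first beat occurs at ``t0_s``.
    """

    interval_ms: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.interval_ms = np.asarray(self.interval_ms, dtype=float)
        if (self.interval_ms <= 0).any():
            raise ValueError("all beat-to-beat intervals must be positive")

    @property
    def n_beats(self) -> int:
        return self.interval_ms.size + 1

    def beat_times_s(self) -> np.ndarray:
        t = self.t0_s + np.concatenate(([0.0], np.cumsum(self.interval_ms) / 1000.0))
        return t

    @property
    def mean_hr_bpm(self) -> float:
        return 60000.0 / float(np.mean(self.interval_ms))


@dataclass(frozen=True)
class DeviceModel:
    """Affine + noise rendering model for one device/stream.

    gain/offset mimic site- and hardware-dependent scaling, ``lag_s`` a
    transport delay on the shared clock, ``noise_sd`` additive white noise
    and ``drift_amp`` slow baseline wander.
    """

    gain: float = 1.0
    offset: float = 0.0
    lag_s: float = 0.0
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    drift_freq_hz: float = 0.15

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not np.isfinite(self.lag_s):
            raise ValueError("lag_s must be finite")


@dataclass(frozen=True)
class ScrShape:
    """Bateman (difference of exponentials) SCR kernel parameters."""

    tau_rise_s: float = 0.75
    tau_decay_s: float = 2.0
    amplitude_uS: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValueError("need 0 < tau_rise_s < tau_decay_s")
        if self.amplitude_uS <= 0:
            raise ValueError("amplitude_uS must be positive")


@dataclass
class PeakSeries:
    """Detected beat/pulse peaks with strictly increasing times (s)."""

    peak_times_s: np.ndarray
    modality: str = "ecg"
    fs_hz: float = 0.0

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size > 1 and not (np.diff(self.peak_times_s) > 0).all():
            raise ValueError("peak times must be strictly increasing")
        if self.modality not in ("ecg", "ppg"):
            raise ValueError(f"modality must be 'ecg' or 'ppg', got {self.modality!r}")

    @property
    def n_peaks(self) -> int:
        return self.peak_times_s.size

    def __len__(self) -> int:
        return self.n_peaks


@dataclass
class CardioParams:
    """Run-level cardiovascular parameters derived from beat intervals.

    ``mean_hr_bpm = 60000 / mean(interval_ms)``; ``sd_intervals_ms`` is the
    sample SD (ddof=1) of intervals (SDNN) and ``rmssd_ms`` the root mean
    square of successive interval differences. Missing values (too few
    intervals) are NaN.
    """

    mean_hr_bpm: float
    sd_intervals_ms: float
    rmssd_ms: float
    n_intervals: int


@dataclass(frozen=True)
class ScrEvent:
    """One detected skin conductance response."""

    onset_s: float
    peak_s: float
    amplitude_uS: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.peak_s:
            raise ValueError("SCR onset must precede its peak")
        if self.amplitude_uS <= 0:
            raise ValueError("SCR amplitude must be positive")


@dataclass
class EdaDecomposition:
    """Tonic/phasic split of a skin conductance signal (μS)."""

    tonic: np.ndarray
    phasic: np.ndarray
    method: str
    fs_hz: float

    def __post_init__(self) -> None:
        self.tonic = np.asarray(self.tonic, dtype=float)
        self.phasic = np.asarray(self.phasic, dtype=float)
        if self.tonic.shape != self.phasic.shape:
            raise ValueError("tonic and phasic must have equal length")


@dataclass
class EdaParams:
    """Run-level electrodermal parameters.

    ``scr_amp_mean_uS`` is NaN when no SCR was detected.
    """

    scl_mean_uS: float
    scl_sd_uS: float
    scr_per_min: float
    scr_amp_mean_uS: float
    duration_min: float


@dataclass(frozen=True)
class QualityThresholds:
    """Signal-quality-index thresholds for 10-s epochs.

    Defaults follow the established wearable-validation SQI: plausible HR
    30–180 bpm, a 3-s cap on the gap between successive peaks (at most one
    missed beat), max/min interval ratio < 2.2 within an epoch, and
    waveform-template correlation floors of 0.66 (ECG) / 0.86 (PPG).
    """

    hr_min_bpm: float = 30.0
    hr_max_bpm: float = 180.0
    max_gap_s: float = 3.0
    max_interval_ratio: float = 2.2
    min_template_corr_ecg: float = 0.66
    min_template_corr_ppg: float = 0.86
    epoch_len_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.hr_min_bpm < self.hr_max_bpm:
            raise ValueError("hr_min_bpm must be below hr_max_bpm")
        for name in ("max_gap_s", "max_interval_ratio", "epoch_len_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_template_corr(self, modality: str) -> float:
        if modality == "ecg":
            return self.min_template_corr_ecg
        if modality == "ppg":
            return self.min_template_corr_ppg
        raise ValueError(f"unknown modality {modality!r}")
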