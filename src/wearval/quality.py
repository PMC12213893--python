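"""Per-epoch signal quality index (SQI) and good-epoch bookkeeping.

Recordings are epoched into fixed 10-s segments. Each epoch must pass
physiological plausibility rules — extrapolated HR in 30–180 bpm, maximum
peak-to-peak gap ≤ 3 s (no more than one missed beat), max/min interval
ratio < 2.2 (HR is not expected to change more than ~10% inside 10 s) —
and a waveform-template correlation floor (0.66 ECG / 0.86 PPG): each beat
window, of width equal to the median beat-to-beat interval, is correlated
against the mean-beat template, and the epoch's mean Pearson r must reach
the modality floor. Failing any rule labels the epoch "bad".

Good epochs are concatenated for parameter computation; to balance the
device comparison, the device with more good epochs is truncated (from
the end of the run) to the other's good-epoch count.

Interval attribution: an interval spanning an epoch boundary belongs to
the epoch of its *later* peak. When good epochs are concatenated, a
spanning interval is kept if the preceding epoch is also good and kept,
and dropped otherwise — rejected-epoch gaps never produce artificial
giant intervals that would corrupt RMSSD.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PeakSeries, QualityThresholds, Recording

__all__ = [
    "RULES",
    "EpochRow",
    "EpochReport",
    "UnusableRunError",
    "epoch_signal",
    "physiological_checks",
    "pulse_template_correlation",
    "assess_quality",
    "harmonize_good_epochs",
]

RULES = ("hr_range", "max_gap", "interval_ratio", "template_corr", "too_few_peaks")


class UnusableRunError(ValueError):
    """Raised when a run has zero good epochs on one device."""


@dataclass
class Epoch:
    index: int
    t_begin_s: float
    t_end_s: float
    signal: np.ndarray
    fs_hz: float
    peak_times_s: np.ndarray  # peaks inside [t_begin, t_end)
    prev_peak_s: float | None  # last peak before the epoch, if any


@dataclass
class EpochRow:
    index: int
    t_begin_s: float
    t_end_s: float
    good: bool
    failed_rules: tuple[str, ...]
    template_corr: float
    intervals_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    first_spans_prev: bool = False


@dataclass
class EpochReport:
    rows: list[EpochRow]
    modality: str
    thresholds: QualityThresholds

    @property
    def n_epochs(self) -> int:
        return len(self.rows)

    @property
    def good_indices(self) -> list[int]:
        return [r.index for r in self.rows if r.good]

    @property
    def good_fraction(self) -> float:
        return len(self.good_indices) / len(self.rows) if self.rows else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [r.index for r in self.rows],
                "t_begin_s": [r.t_begin_s for r in self.rows],
                "t_end_s": [r.t_end_s for r in self.rows],
                "good": [r.good for r in self.rows],
                "failed_rules": ["|".join(r.failed_rules) for r in self.rows],
                "template_corr": [r.template_corr for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "modality": self.modality,
            "good_fraction": self.good_fraction,
            "epochs": self.to_dataframe().to_dict(orient="records"),
        }


def epoch_signal(
    rec: Recording, peaks: PeakSeries, epoch_len_s: float = 10.0
) -> list[Epoch]:
    """Split a recording into contiguous non-overlapping epochs.

    Epochs start at the recording start; the trailing partial epoch is
    discarded. Peaks are assigned to the epoch containing them using
    half-open windows ``[t, t+len)`` (a peak exactly on a boundary belongs
    to the later epoch). A run shorter than one epoch yields an empty
    list with a warning.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    n_epochs = int(np.floor(rec.duration_s / epoch_len_s + 1e-9))
    if n_epochs == 0:
        warnings.warn(
            f"run of {rec.duration_s:.1f}s shorter than one {epoch_len_s:.0f}s epoch",
            stacklevel=2,
        )
        return []
    pt = np.asarray(peaks.peak_times_s, dtype=float)
    samples_per = int(round(epoch_len_s * rec.fs_hz))
    epochs = []
    for k in range(n_epochs):
        t0 = rec.t_start_s + k * epoch_len_s
        t1 = t0 + epoch_len_s
        inside = pt[(pt >= t0 - 1e-12) & (pt < t1 - 1e-12)]
        before = pt[pt < t0 - 1e-12]
        epochs.append(
            Epoch(
                index=k,
                t_begin_s=t0,
                t_end_s=t1,
                signal=rec.data[0, k * samples_per:(k + 1) * samples_per],
                fs_hz=rec.fs_hz,
                peak_times_s=inside,
                prev_peak_s=float(before[-1]) if before.size else None,
            )
        )
    return epochs


def _epoch_intervals_ms(ep: Epoch) -> tuple[np.ndarray, bool]:
    """Intervals attributed to this epoch (later-peak rule)."""
    times = ep.peak_times_s
    spans = False
    if ep.prev_peak_s is not None and times.size:
        times = np.concatenate(([ep.prev_peak_s], times))
        spans = True
    if times.size < 2:
        return np.array([]), False
    return np.diff(times) * 1000.0, spans


def physiological_checks(
    intervals_ms: np.ndarray, thresholds: QualityThresholds | None = None
) -> set[str]:
    """Apply the plausibility rules to one epoch's beat intervals.

    Returns the set of failed rule names; empty set = plausible. Fewer
    than one interval (i.e. < 2 peaks) fails ``too_few_peaks``.
    """
    thr = thresholds or QualityThresholds()
    iv = np.asarray(intervals_ms, dtype=float)
    if iv.size < 1:
        return {"too_few_peaks"}
    failed: set[str] = set()
    hr = 60000.0 / float(np.mean(iv))
    if not thr.hr_min_bpm <= hr <= thr.hr_max_bpm:
        failed.add("hr_range")
    if iv.max() > thr.max_gap_s * 1000.0:
        failed.add("max_gap")
    if iv.max() / iv.min() >= thr.max_interval_ratio:
        failed.add("interval_ratio")
    return failed


def pulse_template_correlation(
    signal: np.ndarray,
    peak_times_s: np.ndarray,
    fs_hz: float,
    t0_s: float = 0.0,
    template: np.ndarray | None = None,
) -> tuple[float, int]:
    """Mean Pearson correlation of each beat window with the beat template.

    Window width = median beat-to-beat interval (in samples, forced odd),
    centered on each peak; windows that would cross the signal edges are
    dropped. The template defaults to the samplewise mean of the usable
    windows (pass ``template`` to correlate against a precomputed one). A
    zero-variance window scores r = 0, counting against quality.

    Returns ``(mean_r, n_windows)``; ``(nan, n)`` when fewer than 2
    usable windows remain.
    """
    pt = np.asarray(peak_times_s, dtype=float)
    if pt.size < 2:
        return float("nan"), 0
    width = int(round(np.median(np.diff(pt)) * fs_hz))
    if width % 2 == 0:
        width += 1
    half = width // 2
    centers = np.round((pt - t0_s) * fs_hz).astype(int)
    windows = [
        signal[c - half:c + half + 1]
        for c in centers
        if c - half >= 0 and c + half + 1 <= signal.size
    ]
    if len(windows) < 2:
        return float("nan"), len(windows)
    w = np.vstack(windows)
    tpl = w.mean(axis=0) if template is None else template[: w.shape[1]]
    tpl_sd = tpl.std()
    rs = []
    for row in w:
        sd = row.std()
        if sd == 0 or tpl_sd == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(row, tpl)[0, 1]))
    return float(np.mean(rs)), len(windows)


def assess_quality(
    rec: Recording,
    peaks: PeakSeries,
    modality: str,
    thresholds: QualityThresholds | None = None,
    template_scope: str = "epoch",
) -> EpochReport:
    """Run the full SQI over a recording: one verdict per 10-s epoch.

    An epoch is bad iff any physiological rule fails or its template
    correlation falls below the modality floor (0.66 ECG / 0.86 PPG).
    ``template_scope="run"`` correlates every epoch's windows against a
    single whole-run template instead of per-epoch templates.
    """
    thr = thresholds or QualityThresholds()
    if template_scope not in ("epoch", "run"):
        raise ValueError("template_scope must be 'epoch' or 'run'")
    corr_floor = thr.min_template_corr(modality)
    epochs = epoch_signal(rec, peaks, thr.epoch_len_s)

    run_template = None
    if template_scope == "run" and peaks.n_peaks >= 2:
        pt = peaks.peak_times_s
        width = int(round(np.median(np.diff(pt)) * rec.fs_hz))
        width += 1 - width % 2
        half = width // 2
        centers = np.round((pt - rec.t_start_s) * rec.fs_hz).astype(int)
        ws = [
            rec.data[0, c - half:c + half + 1]
            for c in centers
            if c - half >= 0 and c + half + 1 <= rec.n_samples
        ]
        if len(ws) >= 2:
            run_template = np.vstack(ws).mean(axis=0)

    rows: list[EpochRow] = []
    for ep in epochs:
        iv, spans = _epoch_intervals_ms(ep)
        failed = physiological_checks(iv, thr)
        r, n_win = pulse_template_correlation(
            ep.signal, ep.peak_times_s, ep.fs_hz, t0_s=ep.t_begin_s, template=run_template
        )
        if np.isnan(r):
            failed.add("too_few_peaks")
        elif r < corr_floor:
            failed.add("template_corr")
        rows.append(
            EpochRow(
                index=ep.index,
                t_begin_s=ep.t_begin_s,
                t_end_s=ep.t_end_s,
                good=not failed,
                failed_rules=tuple(sorted(failed)),
                template_corr=r,
                intervals_ms=iv,
                first_spans_prev=spans,
            )
        )
    return EpochReport(rows=rows, modality=modality, thresholds=thr)


def _concat_intervals(report: EpochReport, kept: list[int]) -> np.ndarray:
    kept_set = set(kept)
    out: list[np.ndarray] = []
    for r in report.rows:
        if r.index not in kept_set:
            continue
        iv = r.intervals_ms
        if iv.size and r.first_spans_prev and (r.index - 1) not in kept_set:
            iv = iv[1:]  # spanning interval crosses a rejected/truncated epoch
        if iv.size:
            out.append(iv)
    return np.concatenate(out) if out else np.array([])


def harmonize_good_epochs(
    report_a: EpochReport, report_b: EpochReport
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize good-epoch counts and concatenate intervals per device.

    The device with more good epochs drops its trailing good epochs so
    both contribute the same count; each device's surviving intervals are
    concatenated in time order. Raises :class:`UnusableRunError` if either
    device has zero good epochs.
    """
    good_a, good_b = report_a.good_indices, report_b.good_indices
    if not good_a or not good_b:
        raise UnusableRunError(
            f"unusable run: {len(good_a)} good epochs on device a, "
            f"{len(good_b)} on device b"
        )
    k = min(len(good_a), len(good_b))
    return (
        _concat_intervals(report_a, good_a[:k]),
        _concat_intervals(report_b, good_b[:k]),
    )
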