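"""Reading, writing, resampling and aligning timestamped recordings.

Two CSV dialects are supported, both UTF-8 with a mandatory header row and
"." decimal separator:

* **wide** — one ``time_s`` column followed by one column per channel;
* **long** — three columns ``time_s, channel, value`` with channel tags
  interleaved row-wise.

Each CSV may carry a JSON sidecar (``<stem>.meta.json``) holding sampling
rate, start time, device id, channel labels and free-form metadata
(including synthetic ground truth); the writer emits it and the reader
restores it when present.

Gap policy: runs of missing samples up to 0.5 s are linearly interpolated
with a logged warning; longer gaps split the recording (the per-epoch
quality gate downstream rejects bad spans anyway).
"""
from __future__ import annotations

import json
import math
import warnings
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import Recording, RunSegment

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_recording_segments",
    "resample_to",
    "align_overlap",
    "slice_run",
    "average_ppg_wavelengths",
]

_DIALECTS = ("wide", "long")
_MAX_INTERP_GAP_S = 0.5


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_recording_csv(
    rec: Recording, path: str | Path, dialect: str = "wide", sidecar: bool = True
) -> Path:
    """Write a recording to CSV (+ JSON metadata sidecar). Returns the path."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    t = rec.times()
    if dialect == "wide":
        df = pd.DataFrame({"time_s": t})
        for label, row in zip(rec.channel_labels, rec.data):
            df[label] = row
    else:
        frames = [
            pd.DataFrame({"time_s": t, "channel": label, "value": row})
            for label, row in zip(rec.channel_labels, rec.data)
        ]
        df = (
            pd.concat(frames)
            .sort_values(["time_s", "channel"], kind="stable")
            .reset_index(drop=True)
        )
    df.to_csv(path, index=False, float_format="%.10g")
    if sidecar:
        meta = {
            "fs_hz": rec.fs_hz,
            "t_start_s": rec.t_start_s,
            "device_id": rec.device_id,
            "channel_labels": rec.channel_labels,
            "meta": rec.meta,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _load_frame(path: Path, dialect: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if dialect == "wide":
        t = df.iloc[:, 0].to_numpy(dtype=float)
        labels = list(df.columns[1:])
        data = df.iloc[:, 1:].to_numpy(dtype=float).T
    else:
        if not {"time_s", "channel", "value"} <= set(df.columns):
            raise ValueError("long dialect requires columns time_s, channel, value")
        wide = df.pivot_table(index="time_s", columns="channel", values="value", sort=True)
        labels = [str(c) for c in wide.columns]
        t = wide.index.to_numpy(dtype=float)
        data = wide.to_numpy(dtype=float).T
    return t, data, labels


def read_recording_segments(path: str | Path, dialect: str = "wide") -> list[Recording]:
    """Read a CSV, splitting at gaps longer than 0.5 s.

    Returns one Recording per contiguous segment; sub-0.5-s gaps inside a
    segment are linearly interpolated with a warning.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    t, data, labels = _load_frame(path, dialect)
    if t.size < 2:
        raise ValueError("recording needs at least 2 samples to infer a sampling rate")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("timestamps are not strictly increasing")

    sidecar = _sidecar_path(path)
    side = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    side_labels = side.get("channel_labels")
    if side_labels and sorted(side_labels) == sorted(labels) and side_labels != labels:
        # the long dialect pivots channels alphabetically; restore the
        # original channel order recorded in the sidecar
        order = [labels.index(lbl) for lbl in side_labels]
        data, labels = data[order], list(side_labels)
    period = 1.0 / side["fs_hz"] if "fs_hz" in side else float(np.median(dt))
    fs = 1.0 / period

    # contiguous segments separated by long gaps
    breaks = np.flatnonzero(dt > _MAX_INTERP_GAP_S + 0.5 * period)
    bounds = [0, *(b + 1 for b in breaks), t.size]
    segments: list[Recording] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ts, ds = t[lo:hi], data[:, lo:hi]
        if ts.size < 2:
            continue
        n = int(round((ts[-1] - ts[0]) * fs)) + 1
        grid = ts[0] + np.arange(n) / fs
        gap_rows = np.flatnonzero(np.diff(ts) > 1.5 * period)
        if n != ts.size or gap_rows.size:
            warnings.warn(
                f"{gap_rows.size} gap(s) > 1 sample period interpolated onto the "
                f"uniform {fs:g} Hz grid",
                stacklevel=2,
            )
            ds = np.vstack([np.interp(grid, ts, row) for row in ds])
        segments.append(
            Recording(
                data=ds,
                fs_hz=fs,
                t_start_s=float(ts[0]),
                channel_labels=side.get("channel_labels", labels),
                device_id=side.get("device_id", ""),
                meta=side.get("meta", {}),
            )
        )
    if not segments:
        raise ValueError(f"no usable segment found in {path}")
    return segments


def read_recording_csv(path: str | Path, dialect: str = "wide") -> Recording:
    """Read a CSV recording; raises if long gaps split it into segments."""
    segments = read_recording_segments(path, dialect)
    if len(segments) > 1:
        raise ValueError(
            f"{path} splits into {len(segments)} segments at gaps > "
            f"{_MAX_INTERP_GAP_S}s; use read_recording_segments()"
        )
    return segments[0]


# ---------------------------------------------------------------------------


def resample_to(rec: Recording, target_fs_hz: float) -> Recording:
    """Resample all channels to ``target_fs_hz``.

    Downsampling first applies a zero-phase 8th-order Butterworth low-pass
    at 0.4 × target rate (anti-aliasing), then a polyphase rational
    resample; non-integer rate ratios are handled via the rational
    approximation, never by silent decimation.
    """
    if target_fs_hz <= 0:
        raise ValueError("target_fs_hz must be positive")
    if math.isclose(target_fs_hz, rec.fs_hz, rel_tol=1e-12):
        return rec.copy()
    data = rec.data
    if target_fs_hz < rec.fs_hz:
        sos = sps.butter(8, 0.4 * target_fs_hz, btype="low", fs=rec.fs_hz, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=1)
    frac = Fraction(target_fs_hz / rec.fs_hz).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(data, up, down, axis=1, padtype="line")
    n_target = int(round(rec.duration_s * target_fs_hz))
    out = out[:, :n_target] if out.shape[1] >= n_target else np.pad(
        out, ((0, 0), (0, n_target - out.shape[1])), mode="edge"
    )
    new = rec.copy()
    new.data = out
    new.fs_hz = target_fs_hz
    return new


def align_overlap(rec_a: Recording, rec_b: Recording) -> tuple[Recording, Recording]:
    """Trim both recordings to their overlapping window on the shared clock."""
    t0 = max(rec_a.t_start_s, rec_b.t_start_s)
    t1 = min(rec_a.t_end_s, rec_b.t_end_s)
    if t1 <= t0:
        raise ValueError(
            f"recordings do not overlap: [{rec_a.t_start_s}, {rec_a.t_end_s}] vs "
            f"[{rec_b.t_start_s}, {rec_b.t_end_s}]"
        )

    def trim(rec: Recording) -> Recording:
        i0 = int(np.ceil((t0 - rec.t_start_s) * rec.fs_hz - 1e-9))
        i1 = int(np.floor((t1 - rec.t_start_s) * rec.fs_hz + 1e-9))
        out = rec.copy()
        out.data = rec.data[:, i0:i1]
        out.t_start_s = rec.t_start_s + i0 / rec.fs_hz
        return out

    return trim(rec_a), trim(rec_b)


def slice_run(rec: Recording, seg: RunSegment) -> Recording:
    """Extract samples in ``[t_begin_s, t_end_s)`` and tag the condition."""
    if seg.t_begin_s < rec.t_start_s - 1e-9 or seg.t_end_s > rec.t_end_s + 1e-9:
        raise ValueError(
            f"segment [{seg.t_begin_s}, {seg.t_end_s}] outside recording "
            f"[{rec.t_start_s}, {rec.t_end_s}]"
        )
    i0 = int(round((seg.t_begin_s - rec.t_start_s) * rec.fs_hz))
    i1 = int(round((seg.t_end_s - rec.t_start_s) * rec.fs_hz))
    if i1 <= i0:
        raise ValueError("zero-length segment")
    out = rec.copy()
    out.data = rec.data[:, i0:i1]
    out.t_start_s = rec.t_start_s + i0 / rec.fs_hz
    out.meta = dict(rec.meta, condition=seg.condition)
    return out


def average_ppg_wavelengths(rec: Recording, normalize: bool = True) -> Recording:
    """Average the three PPG wavelength streams into one signal.

    With ``normalize=True`` (default) each stream is z-scored over the run
    before averaging so no stream dominates by raw scale; ``False`` takes
    the raw samplewise mean. Constant streams z-score to zero.
    """
    if rec.n_channels != 3:
        raise ValueError(f"expected exactly 3 PPG channels, got {rec.n_channels}")
    data = rec.data
    if normalize:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        data = (data - mu) / sd
    out = rec.copy()
    out.data = data.mean(axis=0, keepdims=True)
    out.channel_labels = ["ppg_avg"]
    return out
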