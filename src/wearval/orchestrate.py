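"""Config-driven end-to-end validation runs.

A study run loads (or simulates) paired reference/wearable recordings for
each participant × condition, executes the configured grid of cardio and
EDA preprocessing pipelines, gates signal quality per 10-s epoch,
computes the run-level parameters, and assesses inter-device agreement
(Bland-Altman ratio per parameter, cross-correlation of the EDA series).
Failures of a single pipeline on a single run never abort the grid; such
pipelines are marked incomplete and excluded from selection.

In simulate mode the whole report is a pure function of (config, seed):
rerunning writes a byte-identical JSON report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from . import cardio, eda, quality, synth
from .io import average_ppg_wavelengths, read_recording_csv, resample_to
from .types import DeviceModel, QualityThresholds, Recording, ScrShape

logger = logging.getLogger("wearval")

__all__ = [
    "CardioPipelineSpec",
    "EdaPipelineSpec",
    "SimSettings",
    "StudyConfig",
    "run_validation",
    "emit_report",
    "validate_report",
]

CARDIO_PARAM_IDS = ("mean_hr_bpm", "sd_intervals_ms", "rmssd_ms")
EDA_PARAM_IDS = ("scl_mean_uS", "scr_per_min", "scr_amp_mean_uS")

#: parameters log10-transformed before Bland-Altman differencing by default
DEFAULT_LOG10_PARAMS = (
    "mean_hr_bpm",
    "sd_intervals_ms",
    "rmssd_ms",
    "scl_mean_uS",
    "scr_amp_mean_uS",
)


@dataclass(frozen=True)
class CardioPipelineSpec:
    ecg_clean: str = "elgendi_ecg"
    ecg_peaks: str = "nabian_window"
    ppg_clean: str = "langevin_ppg"
    ppg_peaks: str = "elgendi_dual_ma"

    @property
    def id(self) -> str:
        return f"ecg:{self.ecg_clean}+{self.ecg_peaks}|ppg:{self.ppg_clean}+{self.ppg_peaks}"


@dataclass(frozen=True)
class EdaPipelineSpec:
    clean: str = "biosppy5hz"
    decomp: str = "highpass005"
    peaks: str = "nabian"

    @property
    def id(self) -> str:
        return f"{self.clean}|{self.decomp}|{self.peaks}"


@dataclass
class SimSettings:
    """Conditions emulated by the synthetic study.

    Defaults mirror the study setting: a 1000 Hz reference ECG + palm EDA
    against a 100 Hz three-wavelength PPG + 15 Hz arm EDA; resting-range
    SCR rate (2/min), moderate short-term HRV, and an arm EDA site with
    markedly lower gain than the palm.
    """

    run_duration_s: float = 180.0
    base_hr_range_bpm: tuple[float, float] = (55.0, 85.0)
    hrv_lf_amp_ms: float = 25.0
    hrv_hf_amp_ms: float = 35.0
    hrv_jitter_sd_ms: float = 8.0
    hr_bias_bpm: float = 0.0  # wearable HR measurement bias
    ecg_fs_hz: float = 1000.0
    ppg_fs_hz: float = 100.0
    ecg_noise_sd: float = 0.02
    ppg_noise_sd: float = 0.03
    pulse_delay_s: float = 0.2
    eda_fs_ref_hz: float = 1000.0
    eda_fs_wear_hz: float = 15.0
    scr_rate_per_min: float = 2.0
    scr_amp_mean_uS: float = 0.4
    tonic_range_uS: tuple[float, float] = (6.0, 10.0)
    eda_wear_gain: float = 0.35
    eda_wear_offset_uS: float = -0.5
    eda_noise_ref_sd: float = 0.01
    eda_noise_wear_sd: float = 0.02


@dataclass
class StudyConfig:
    mode: str = "simulate"  # or "csv"
    n_participants: int = 4
    conditions: tuple[str, ...] = ("easy", "hard")
    seed: int = 0
    sim: SimSettings = field(default_factory=SimSettings)
    cardio_pipelines: list[CardioPipelineSpec] = field(
        default_factory=lambda: [
            CardioPipelineSpec(),
            CardioPipelineSpec("nk_default", "brammer", "elgendi_ppg", "elgendi_dual_ma"),
        ]
    )
    eda_pipelines: list[EdaPipelineSpec] = field(
        default_factory=lambda: [
            EdaPipelineSpec(),
            EdaPipelineSpec("nk3hz", "highpass005", "nk_default"),
            EdaPipelineSpec("biosppy5hz", "median4s", "kim"),
        ]
    )
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    log10_params: tuple[str, ...] = DEFAULT_LOG10_PARAMS
    boundaries: dict = field(default_factory=dict)
    csv_runs: list[dict] = field(default_factory=list)  # csv mode: per-run file paths
    out_dir: str = "wearval_out"

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cardio_pipelines"] = [dataclasses.asdict(p) for p in self.cardio_pipelines]
        d["eda_pipelines"] = [dataclasses.asdict(p) for p in self.eda_pipelines]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            for key in ("base_hr_range_bpm", "tonic_range_uS"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimSettings(**sim)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = QualityThresholds(**d["thresholds"])
        if "cardio_pipelines" in d:
            d["cardio_pipelines"] = [
                CardioPipelineSpec(**p) if isinstance(p, dict) else p
                for p in d["cardio_pipelines"]
            ]
        if "eda_pipelines" in d:
            d["eda_pipelines"] = [
                EdaPipelineSpec(**p) if isinstance(p, dict) else p
                for p in d["eda_pipelines"]
            ]
        for key in ("conditions", "log10_params"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulation of one run


@dataclass
class RunData:
    participant: int
    condition: str
    ecg: Recording
    ppg: Recording
    eda_ref: Recording
    eda_wear: Recording
    duration_s: float


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_run(cfg: StudyConfig, participant: int, condition: str) -> RunData:
    """Simulate one participant × condition pair of device recordings."""
    sim = cfg.sim
    root = np.random.SeedSequence(
        entropy=cfg.seed,
        spawn_key=(participant, cfg.conditions.index(condition)),
    )
    s_traits, s_rr, s_ecg, s_ppg, s_eda, s_events = (
        _child_seed(c) for c in root.spawn(6)
    )
    rng = np.random.default_rng(s_traits)
    lo, hi = sim.base_hr_range_bpm
    base_hr = float(rng.uniform(lo, hi))
    # hard condition: mild workload response (higher HR, more SCRs)
    cond_idx = cfg.conditions.index(condition)
    hr = base_hr + 4.0 * cond_idx
    scr_rate = sim.scr_rate_per_min * (1.0 + 0.5 * cond_idx)

    var = synth.RRVariability(
        lf_amp_ms=sim.hrv_lf_amp_ms,
        hf_amp_ms=sim.hrv_hf_amp_ms,
        jitter_sd_ms=sim.hrv_jitter_sd_ms,
    )
    rr = synth.simulate_rr_series(sim.run_duration_s, hr, var, seed=s_rr)
    ecg = synth.render_ecg(
        rr,
        sim.ecg_fs_hz,
        DeviceModel(noise_sd=sim.ecg_noise_sd),
        duration_s=sim.run_duration_s,
        seed=s_ecg,
    )
    # wearable HR measurement bias: scale intervals so mean HR = hr + bias
    rr_wear = rr
    if sim.hr_bias_bpm:
        scale = rr.mean_hr_bpm / (rr.mean_hr_bpm + sim.hr_bias_bpm)
        rr_wear = synth.RRSeries(rr.interval_ms * scale, t0_s=rr.t0_s)
    ppg = synth.render_ppg(
        rr_wear,
        sim.ppg_fs_hz,
        devices=(
            DeviceModel(gain=1.0, noise_sd=sim.ppg_noise_sd),
            DeviceModel(gain=0.8, noise_sd=sim.ppg_noise_sd),
            DeviceModel(gain=0.9, noise_sd=sim.ppg_noise_sd),
        ),
        pulse_delay_s=sim.pulse_delay_s,
        duration_s=sim.run_duration_s,
        seed=s_ppg,
    )

    ev_rng = np.random.default_rng(s_events)
    n_events = ev_rng.poisson(scr_rate * sim.run_duration_s / 60.0)
    times = np.sort(ev_rng.uniform(5.0, sim.run_duration_s - 10.0, size=n_events))
    events = [
        (
            float(t),
            ScrShape(
                tau_rise_s=0.75,
                tau_decay_s=2.0,
                amplitude_uS=float(ev_rng.lognormal(np.log(sim.scr_amp_mean_uS), 0.3)),
            ),
        )
        for t in times
    ]
    tonic = float(rng.uniform(*sim.tonic_range_uS))
    eda_ref, eda_wear = synth.render_eda_pair(
        sim.run_duration_s,
        sim.eda_fs_ref_hz,
        sim.eda_fs_wear_hz,
        tonic_level_uS=tonic,
        tonic_slope_uS_per_s=0.002,
        scr_events=events,
        device_a=DeviceModel(noise_sd=sim.eda_noise_ref_sd),
        device_b=DeviceModel(
            gain=sim.eda_wear_gain,
            offset=sim.eda_wear_offset_uS,
            noise_sd=sim.eda_noise_wear_sd,
        ),
        seed=s_eda,
    )
    return RunData(participant, condition, ecg, ppg, eda_ref, eda_wear, sim.run_duration_s)


def _load_csv_run(entry: dict) -> RunData:
    return RunData(
        participant=int(entry["participant"]),
        condition=str(entry["condition"]),
        ecg=read_recording_csv(entry["ecg"], entry.get("dialect", "wide")),
        ppg=read_recording_csv(entry["ppg"], entry.get("dialect", "wide")),
        eda_ref=read_recording_csv(entry["eda_ref"], entry.get("dialect", "wide")),
        eda_wear=read_recording_csv(entry["eda_wear"], entry.get("dialect", "wide")),
        duration_s=float(entry.get("duration_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# per-run pipeline execution


def process_cardio_run(
    run: RunData, pipe: CardioPipelineSpec, thresholds: QualityThresholds
) -> dict:
    """Run one cardio pipeline on one run; returns per-device parameters."""
    ecg100 = resample_to(run.ecg, 100.0)
    ecg_sig = cardio.clean_cardio(ecg100.data[0], ecg100.fs_hz, pipe.ecg_clean)
    ecg_clean_rec = ecg100.copy()
    ecg_clean_rec.data = ecg_sig[np.newaxis, :]
    ecg_peaks = cardio.detect_peaks(
        ecg_sig, ecg100.fs_hz, pipe.ecg_peaks, modality="ecg", t0_s=ecg100.t_start_s
    )
    rep_ecg = quality.assess_quality(ecg_clean_rec, ecg_peaks, "ecg", thresholds)

    ppg_avg = average_ppg_wavelengths(run.ppg)
    ppg_sig = cardio.clean_cardio(ppg_avg.data[0], ppg_avg.fs_hz, pipe.ppg_clean)
    ppg_clean_rec = ppg_avg.copy()
    ppg_clean_rec.data = ppg_sig[np.newaxis, :]
    ppg_peaks = cardio.detect_peaks(
        ppg_sig, ppg_avg.fs_hz, pipe.ppg_peaks, modality="ppg", t0_s=ppg_avg.t_start_s
    )
    rep_ppg = quality.assess_quality(ppg_clean_rec, ppg_peaks, "ppg", thresholds)

    iv_ecg, iv_ppg = quality.harmonize_good_epochs(rep_ecg, rep_ppg)
    par_ecg = cardio.cardio_parameters(iv_ecg)
    par_ppg = cardio.cardio_parameters(iv_ppg)
    return {
        "reference": par_ecg,
        "wearable": par_ppg,
        "sqi_good_fraction": {
            "reference": rep_ecg.good_fraction,
            "wearable": rep_ppg.good_fraction,
        },
        "epoch_reports": {"reference": rep_ecg, "wearable": rep_ppg},
    }


def process_eda_run(run: RunData, pipe: EdaPipelineSpec) -> dict:
    """Run one EDA pipeline on one run; returns parameters + cross-correlation."""
    ref15 = resample_to(run.eda_ref, run.eda_wear.fs_hz)
    n = min(ref15.n_samples, run.eda_wear.n_samples)
    sig_ref = eda.clean_eda(ref15.data[0, :n], ref15.fs_hz, pipe.clean)
    sig_wear = eda.clean_eda(run.eda_wear.data[0, :n], run.eda_wear.fs_hz, pipe.clean)
    out = {}
    for name, sig, fs in (
        ("reference", sig_ref, ref15.fs_hz),
        ("wearable", sig_wear, run.eda_wear.fs_hz),
    ):
        dec = eda.decompose_eda(sig, fs, pipe.decomp)
        events = eda.detect_scrs(dec.phasic, fs, pipe.peaks)
        duration = run.duration_s or n / fs
        out[name] = eda.eda_parameters(dec, events, duration)
    xc = ag.cross_correlate(sig_ref, sig_wear, max_lag_samples=8)
    out["cross_correlation"] = {
        "best_lag": xc.best_lag,
        "best_coefficient": xc.best_coefficient,
    }
    return out


# ---------------------------------------------------------------------------
# study-level orchestration


def _params_to_pairs(per_run: list[dict], param_ids, device_a="wearable", device_b="reference"):
    """Collect complete (wearable, reference) pairs per parameter id."""
    pairs = {}
    for pid in param_ids:
        a = np.array([getattr(r[device_a], pid) for r in per_run], dtype=float)
        b = np.array([getattr(r[device_b], pid) for r in per_run], dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        pairs[pid] = (a[ok], b[ok])
    return pairs


def run_validation(cfg: StudyConfig) -> dict:
    """Execute the full study grid and return the validation report dict."""
    if not cfg.cardio_pipelines or not cfg.eda_pipelines:
        raise ValueError("need at least one pipeline per modality")
    if cfg.mode not in ("simulate", "csv"):
        raise ValueError(f"unknown mode {cfg.mode!r}")

    if cfg.mode == "simulate":
        runs = [
            simulate_run(cfg, p, c)
            for c in cfg.conditions
            for p in range(cfg.n_participants)
        ]
    else:
        if not cfg.csv_runs:
            raise ValueError("csv mode requires csv_runs entries")
        runs = [_load_csv_run(e) for e in cfg.csv_runs]

    failures: list[dict] = []
    report: dict = {
        "provenance": {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "mode": cfg.mode,
            "n_participants": cfg.n_participants,
            "conditions": list(cfg.conditions),
        },
        "sqi": {},
        "cardio": {},
        "eda": {},
        "cross_correlation": {},
        "plausibility": {},
        "selected": {},
        "failures": failures,
    }

    # ---- cardio grid ----
    cardio_complete: dict[str, dict[str, list[dict]]] = {}
    for pipe in cfg.cardio_pipelines:
        by_cond: dict[str, list[dict]] = {c: [] for c in cfg.conditions}
        ok = True
        for run in runs:
            try:
                by_cond[run.condition].append(
                    process_cardio_run(run, pipe, cfg.thresholds)
                )
            except Exception as exc:  # error isolation per pipeline × run
                ok = False
                failures.append(
                    {
                        "stage": "cardio",
                        "pipeline": pipe.id,
                        "participant": run.participant,
                        "condition": run.condition,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
                logger.warning("cardio pipeline %s failed on run %s/%s: %s",
                               pipe.id, run.participant, run.condition, exc)
        if ok:
            cardio_complete[pipe.id] = by_cond

    for pid, by_cond in cardio_complete.items():
        report["cardio"][pid] = {}
        for cond, results in by_cond.items():
            pairs = _params_to_pairs(results, CARDIO_PARAM_IDS)
            cond_report = {}
            for param, (a, b) in pairs.items():
                if a.size < 2:
                    cond_report[param] = {"error": "fewer than 2 complete pairs"}
                    continue
                transform = "log10" if param in cfg.log10_params else "none"
                res = ag.bland_altman_ratio(a, b, transform=transform, label=param)
                cond_report[param] = res.to_dict()
                # untransformed differences for pipeline selection / plots
                cond_report[param]["raw_mean_diff"] = float(np.mean(a - b))
                cond_report[param]["raw_diffs"] = (a - b).tolist()
            report["cardio"][pid][cond] = cond_report
            report["sqi"].setdefault(pid, {})[cond] = {
                "reference_good_pct": 100.0
                * float(np.mean([r["sqi_good_fraction"]["reference"] for r in results])),
                "wearable_good_pct": 100.0
                * float(np.mean([r["sqi_good_fraction"]["wearable"] for r in results])),
            }

    # cardio pipeline selection: highest mean good-epoch percentage
    if report["sqi"]:
        def mean_sqi(pid: str) -> float:
            vals = [
                v["reference_good_pct"] + v["wearable_good_pct"]
                for v in report["sqi"][pid].values()
            ]
            return float(np.mean(vals))

        best = sorted(report["sqi"], key=lambda p: (-mean_sqi(p), p))[0]
        report["selected"]["cardio"] = best

    # ---- EDA grid ----
    eda_complete: dict[str, dict[str, list[dict]]] = {}
    for pipe in cfg.eda_pipelines:
        by_cond = {c: [] for c in cfg.conditions}
        ok = True
        for run in runs:
            try:
                by_cond[run.condition].append(process_eda_run(run, pipe))
            except Exception as exc:
                ok = False
                failures.append(
                    {
                        "stage": "eda",
                        "pipeline": pipe.id,
                        "participant": run.participant,
                        "condition": run.condition,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
                logger.warning("eda pipeline %s failed on run %s/%s: %s",
                               pipe.id, run.participant, run.condition, exc)
        if ok:
            eda_complete[pipe.id] = by_cond

    eligible_diffs: dict[str, np.ndarray] = {}
    for pid, by_cond in eda_complete.items():
        all_results = [r for results in by_cond.values() for r in results]
        verdict = eda.screen_pipeline_plausibility(
            [r["reference"] for r in all_results]
        )
        report["plausibility"][pid] = verdict.to_dict()
        report["cross_correlation"][pid] = {
            cond: {
                "mean_best_coefficient": float(
                    np.mean([r["cross_correlation"]["best_coefficient"] for r in results])
                ),
                "best_lags": [r["cross_correlation"]["best_lag"] for r in results],
            }
            for cond, results in by_cond.items()
        }
        if verdict.excluded:
            continue
        report["eda"][pid] = {}
        for cond, results in by_cond.items():
            pairs = _params_to_pairs(results, EDA_PARAM_IDS)
            cond_report = {}
            for param, (a, b) in pairs.items():
                if a.size < 2:
                    cond_report[param] = {"error": "fewer than 2 complete pairs"}
                    continue
                transform = "log10" if param in cfg.log10_params else "none"
                try:
                    res = ag.bland_altman_ratio(a, b, transform=transform, label=param)
                except ValueError as exc:
                    cond_report[param] = {"error": str(exc)}
                    continue
                cond_report[param] = res.to_dict()
                cond_report[param]["raw_mean_diff"] = float(np.mean(a - b))
            report["eda"][pid][cond] = cond_report
        # selection statistic: per-run SCL mean differences (wearable − reference)
        diffs = np.array(
            [
                r["wearable"].scl_mean_uS - r["reference"].scl_mean_uS
                for results in by_cond.values()
                for r in results
            ]
        )
        if diffs.size >= 2:
            eligible_diffs[pid] = diffs

    if eligible_diffs:
        report["selected"]["eda"] = ag.select_pipeline(eligible_diffs)

    return report


# ---------------------------------------------------------------------------
# report emission


_REQUIRED_KEYS = (
    "provenance",
    "sqi",
    "cardio",
    "eda",
    "cross_correlation",
    "plausibility",
    "selected",
    "failures",
)


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys/types)."""
    missing = [k for k in _REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required keys: {missing}")
    if not isinstance(report["failures"], list):
        raise ValueError("report['failures'] must be a list")
    for section in ("cardio", "eda"):
        for pid, by_cond in report[section].items():
            for cond, params in by_cond.items():
                for param, entry in params.items():
                    if "error" not in entry and "bar_value" not in entry:
                        raise ValueError(
                            f"{section}/{pid}/{cond}/{param}: neither result nor error"
                        )


def _agreement_rows(section: dict, modality: str) -> list[dict]:
    rows = []
    for pid, by_cond in section.items():
        for cond, params in by_cond.items():
            for param, entry in params.items():
                if "error" in entry:
                    continue
                rows.append(
                    {
                        "modality": modality,
                        "pipeline": pid,
                        "condition": cond,
                        "parameter": param,
                        **{k: v for k, v in entry.items() if k != "raw_diffs"},
                    }
                )
    return rows


def emit_report(report: dict, out_dir: str | Path, formats=("json", "csv")) -> list[Path]:
    """Write the validation report to disk; returns the written paths."""
    validate_report(report)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report, indent=1, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        rows = _agreement_rows(report["cardio"], "cardio") + _agreement_rows(
            report["eda"], "eda"
        )
        p = out_dir / "agreement.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

        sqi_rows = [
            {"pipeline": pid, "condition": cond, **vals}
            for pid, by_cond in report["sqi"].items()
            for cond, vals in by_cond.items()
        ]
        p = out_dir / "sqi_summary.csv"
        pd.DataFrame(sqi_rows).to_csv(p, index=False)
        written.append(p)

        xc_rows = [
            {
                "pipeline": pid,
                "condition": cond,
                "mean_best_coefficient": vals["mean_best_coefficient"],
            }
            for pid, by_cond in report["cross_correlation"].items()
            for cond, vals in by_cond.items()
        ]
        p = out_dir / "cross_correlation.csv"
        pd.DataFrame(xc_rows).to_csv(p, index=False)
        written.append(p)
    return written
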