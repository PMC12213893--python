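"""Bland-Altman agreement statistics, cross-correlation, pipeline choice.

The central quantity is the Bland-Altman ratio

    BAr = 1.96 · SD(differences) / |A_pm|,

where the differences are per-run device differences of one parameter and
``A_pm`` is the average of the pairwise means. The 1.96·SD half-width of
the 95% limits of agreement is expressed relative to the magnitude of the
parameter itself: BAr < 0.01 is excellent agreement, 0.01–0.1 good,
0.1–0.2 moderate, > 0.2 insufficient. Parameters spanning decades (HR,
interval SD, RMSSD, SCL, SCR amplitude) are log10-transformed per device
value before differencing.

The magnitude |A_pm| is used in the denominator so BAr ≥ 0 regardless of
the sign of the mean level; the signed ratio is also exposed on the
result for inspection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "LimitsOfAgreement",
    "AgreementResult",
    "CrossCorrResult",
    "limits_of_agreement",
    "categorize_bar",
    "bland_altman_ratio",
    "log10_params",
    "plausibility_boundaries",
    "cross_correlate",
    "select_pipeline",
    "DEFAULT_BOUNDARIES",
]

#: z-quantile defining the 95% limits of agreement.
Z_95 = 1.96

#: annotation-only plausibility bands per parameter id (low, high), in the
#: parameter's own units; ±5 bpm for mean HR, others configurable.
DEFAULT_BOUNDARIES: dict[str, tuple[float, float]] = {
    "mean_hr_bpm": (-5.0, 5.0),
}

_CATEGORIES = ("excellent", "good", "moderate", "insufficient")


@dataclass(frozen=True)
class LimitsOfAgreement:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class AgreementResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    a_pm: float
    bar_value: float
    bar_signed: float
    category: str
    n_pairs: int
    transform: str

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "a_pm": self.a_pm,
            "bar_value": self.bar_value,
            "category": self.category,
            "n_pairs": self.n_pairs,
            "transform": self.transform,
        }


@dataclass(frozen=True)
class CrossCorrResult:
    lags: np.ndarray
    coefficients: np.ndarray
    best_lag: int
    best_coefficient: float


def limits_of_agreement(diffs: np.ndarray) -> LimitsOfAgreement:
    """Mean difference, sample SD and 95% limits of agreement.

    LoA = mean ± 1.96 × sample SD (ddof=1). Requires at least 2
    differences.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError(f"need >= 2 differences, got {d.size}")
    m = float(np.mean(d))
    s = float(np.std(d, ddof=1))
    return LimitsOfAgreement(m, s, m - Z_95 * s, m + Z_95 * s)


def categorize_bar(bar: float) -> str:
    """Map a Bland-Altman ratio to its agreement category.

    Boundary convention: [0, 0.01) excellent, [0.01, 0.1] good,
    (0.1, 0.2] moderate, (0.2, inf) insufficient.
    """
    if bar < 0:
        raise ValueError("BAr must be non-negative")
    if bar < 0.01:
        return "excellent"
    if bar <= 0.1:
        return "good"
    if bar <= 0.2:
        return "moderate"
    return "insufficient"


def log10_params(values: np.ndarray, label: str = "") -> np.ndarray:
    """Elementwise log10 with an informative error on non-positive values."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        bad = np.flatnonzero(v <= 0)
        raise ValueError(
            f"log10 transform{f' of {label}' if label else ''}: non-positive value(s) "
            f"at run index {bad.tolist()} (values {v[bad].tolist()})"
        )
    return np.log10(v)


def bland_altman_ratio(
    values_a: np.ndarray,
    values_b: np.ndarray,
    transform: str = "none",
    label: str = "",
) -> AgreementResult:
    """Bland-Altman ratio and agreement category for paired device values.

    Differences are ``a − b`` (by convention, wearable minus reference).
    ``transform="log10"`` log-transforms each device's values before
    differencing. ``A_pm`` is the average of the pairwise means; the
    reported BAr uses its magnitude, keeping the ratio non-negative.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value arrays must have equal shape")
    if a.size < 2:
        raise ValueError(f"need >= 2 pairs, got {a.size}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("pairs must be complete; found NaN values")
    if transform == "log10":
        a = log10_params(a, label=f"{label} (device a)" if label else "device a")
        b = log10_params(b, label=f"{label} (device b)" if label else "device b")
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    loa = limits_of_agreement(a - b)
    a_pm = float(np.mean((a + b) / 2.0))
    if a_pm == 0:
        raise ZeroDivisionError("undefined Bland-Altman ratio: average of pairwise means is 0")
    bar_signed = Z_95 * loa.sd_diff / a_pm
    bar = Z_95 * loa.sd_diff / abs(a_pm)
    return AgreementResult(
        mean_diff=loa.mean_diff,
        sd_diff=loa.sd_diff,
        loa_low=loa.loa_low,
        loa_high=loa.loa_high,
        a_pm=a_pm,
        bar_value=bar,
        bar_signed=bar_signed,
        category=categorize_bar(bar),
        n_pairs=int(a.size),
        transform=transform,
    )


def plausibility_boundaries(
    parameter_id: str, config: dict[str, tuple[float, float]] | None = None
) -> tuple[float, float]:
    """Annotation-only plausibility band for a parameter.

    These bands (±10% of biologically plausible values; ±5 bpm for mean
    HR) are attached to plots and reports for interpretability only —
    they are never used to include or exclude data.
    """
    registry = dict(DEFAULT_BOUNDARIES)
    if config:
        registry.update(config)
    if parameter_id not in registry:
        raise KeyError(
            f"no plausibility boundaries registered for {parameter_id!r}; "
            f"known: {sorted(registry)}"
        )
    lo, hi = registry[parameter_id]
    return float(lo), float(hi)


def cross_correlate(
    sig_a: np.ndarray, sig_b: np.ndarray, max_lag_samples: int = 8
) -> CrossCorrResult:
    """Normalized cross-correlation of two equally sampled series.

    Both series are linearly detrended and z-scored; the coefficient at
    lag k is ``sum(a[t]·b[t+k]) / n`` over the truncated (non-circular)
    overlap, so the lag-0 autocorrelation of a series with itself is
    exactly 1. Positive ``best_lag`` means the second series is delayed
    relative to the first. Constant input raises (zero variance).
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length (align/resample first)")
    if a.size <= 10 * max_lag_samples:
        raise ValueError(
            f"series length {a.size} too short for max_lag={max_lag_samples} "
            f"(need > {10 * max_lag_samples})"
        )
    scale_a = max(1.0, float(np.abs(a).max()))
    scale_b = max(1.0, float(np.abs(b).max()))
    a = sps.detrend(a, type="linear")
    b = sps.detrend(b, type="linear")
    if a.std() <= 1e-12 * scale_a or b.std() <= 1e-12 * scale_b:
        raise ValueError("constant series: cross-correlation undefined (zero variance)")
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    n = a.size
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    coeffs = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            coeffs[i] = float(np.dot(a[: n - k], b[k:])) / n
        else:
            coeffs[i] = float(np.dot(a[-k:], b[: n + k])) / n
    best = int(np.argmax(coeffs))
    return CrossCorrResult(
        lags=lags,
        coefficients=coeffs,
        best_lag=int(lags[best]),
        best_coefficient=float(coeffs[best]),
    )


def select_pipeline(results: dict[str, np.ndarray]) -> str:
    """Choose the pipeline with the smallest SD of per-run differences.

    The most consistent inter-device differences across runs mark the
    most robust processing for signal comparison. Ties break
    lexicographically by pipeline id with a warning.
    """
    if not results:
        raise ValueError("no eligible pipeline to select from")
    sds = {
        pid: float(np.std(np.asarray(d, dtype=float), ddof=1))
        for pid, d in results.items()
    }
    best_sd = min(sds.values())
    winners = sorted(pid for pid, sd in sds.items() if sd == best_sd)
    if len(winners) > 1:
        warnings.warn(
            f"pipeline selection tie at SD={best_sd:g} among {winners}; "
            f"choosing {winners[0]!r} lexicographically",
            stacklevel=2,
        )
    return winners[0]
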