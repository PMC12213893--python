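# wearval

Criterion-validity analysis of wearable physiological sensors against
reference devices.

When a wrist- or arm-worn device (photoplethysmography for pulse, a dry
electrode pair for skin conductance) is proposed as a substitute for the
laboratory standard (electrocardiography, palmar electrodermal recording),
the question is not whether the two signals look similar but whether the
*parameters researchers actually use* — mean heart rate (HR), beat-interval
SD (SDNN), RMSSD, skin conductance level (SCL), skin conductance response
(SCR) rate and amplitude — agree across devices run by run. `wearval`
implements that validation pipeline end to end:

1. **Synthetic paired recordings** with known ground truth: a shared beat
   train rendered as a 1000 Hz ECG and a 100 Hz three-wavelength PPG, and a
   shared electrodermal process (tonic drift + Bateman-shaped SCRs) rendered
   through two devices with different gain/offset/noise (palm vs. upper arm).
2. **Preprocessing grids** mirroring the methods used across the wearable
   validation literature: per-method cleaning filters, four ECG peak
   detectors (absolute-gradient, dual moving average, sliding-window,
   second-derivative), three EDA tonic/phasic decompositions and four SCR
   detectors — all addressable by stable string ids.
3. **Signal quality index (SQI)**: each 10-s epoch must show an
   extrapolated HR in 30–180 bpm, no peak gap over 3 s, a max/min interval
   ratio below 2.2, and a beat-template correlation of at least 0.66 (ECG)
   or 0.86 (PPG). Good epochs are concatenated and both devices trimmed to
   equal good-epoch counts.
4. **Agreement statistics**: Bland-Altman limits of agreement and the
   Bland-Altman ratio

   BAr = 1.96 · SD(differences) / |A_pm|,

   where A_pm is the average of the pairwise means. BAr < 0.01 is excellent
   agreement, 0.01–0.1 good, 0.1–0.2 moderate, > 0.2 insufficient.
   Parameters spanning decades are log10-transformed per device value
   before differencing. Lagged cross-correlation (±8 samples, i.e. ±0.53 s
   at 15 Hz) compares the EDA time series directly. A plausibility screen
   drops SCR pipelines averaging more than 30 responses/min or near-zero
   amplitudes, and the pipeline with the smallest SD of inter-device
   differences is selected.

## Worked example

```python
import numpy as np
from wearval import synth, cardio, quality, agreement
from wearval.io import resample_to
from wearval.types import DeviceModel

var = synth.RRVariability(lf_amp_ms=25, hf_amp_ms=35, jitter_sd_ms=8)
rr = synth.simulate_rr_series(180, 72, var, seed=1)
ecg = synth.render_ecg(rr, 1000, DeviceModel(noise_sd=0.05), duration_s=180, seed=2)

ecg100 = resample_to(ecg, 100.0)
sig = cardio.clean_cardio(ecg100.data[0], 100.0, "elgendi_ecg")
peaks = cardio.detect_peaks(sig, 100.0, "nabian_window")
rec = ecg100.copy(); rec.data = sig[None, :]
report = quality.assess_quality(rec, peaks, "ecg")
params = cardio.cardio_parameters(cardio.peak_intervals(peaks))
print(f"good epochs: {100 * report.good_fraction:.1f}%")
print(f"mean HR:  {params.mean_hr_bpm:.1f} bpm  (ground truth {rr.mean_hr_bpm:.1f})")
print(f"SDNN:     {params.sd_intervals_ms:.1f} ms")
print(f"RMSSD:    {params.rmssd_ms:.1f} ms")

a = np.array([71.2, 64.8, 80.3, 75.1])   # wearable per-run mean HR
b = np.array([71.0, 64.9, 80.6, 75.0])   # reference per-run mean HR
res = agreement.bland_altman_ratio(a, b, transform="log10")
print(f"BAr = {res.bar_value:.4f} -> {res.category}")
```

prints

```
good epochs: 100.0%
mean HR:  72.1 bpm  (ground truth 72.1)
SDNN:     31.0 ms
RMSSD:    33.2 ms
BAr = 0.0013 -> excellent
```

Every epoch of the clean 3-minute synthetic ECG passes the quality rules;
the detected mean HR matches the generator's ground truth to 0.1 bpm; and
four near-identical per-run HR pairs yield a Bland-Altman ratio far below
the 0.01 "excellent" threshold.

Full studies run through the orchestrator (`wearval.run_validation`) or the
CLI:

```sh
wearval simulate --seed 1 --out sim_data      # paired CSVs + ground truth
wearval validate --seed 1 --out study_out     # grid run -> report.json + CSVs
```

## Layout

| module | contents |
| --- | --- |
| `wearval.synth` | paired-device simulator, Bateman kernel, artifact injection |
| `wearval.io` | CSV dialects + JSON sidecars, resampling, alignment, PPG averaging |
| `wearval.cardio` | cleaning filters, peak detectors, HR/SDNN/RMSSD |
| `wearval.quality` | 10-s epoch SQI, template correlation, good-epoch harmonization |
| `wearval.eda` | EDA cleaning, tonic/phasic decomposition, SCR detection, screens |
| `wearval.agreement` | limits of agreement, BAr + categories, cross-correlation, selection |
| `wearval.orchestrate` | config-driven grid runs, reports, error isolation |
| `wearval.cli` | `wearval simulate / validate / report` |

See `docs/methods.md` for the modeling choices and their rationale.
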