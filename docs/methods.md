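# Methods

This note documents the models, defaults and design choices behind
`wearval`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the synthetic
tests do and do not demonstrate.

## The validation procedure

Two devices record the same physiology on a shared clock: a reference
system (ECG at 1000 Hz, palmar EDA at 1000 Hz) and a wearable (PPG at
100 Hz storing green/red/infrared wavelength streams separately, EDA at
15 Hz). Per participant and workload condition, each signal passes a
preprocessing pipeline, a per-epoch quality gate, and parameter
extraction; per-run parameter pairs then enter the agreement analysis.

Reference signals are downsampled to the wearable's rate before
comparison (ECG → 100 Hz, EDA → 15 Hz), and the three PPG wavelengths are
averaged to a single stream — by default after z-scoring each stream over
the run, because the raw streams have device-dependent scales and a raw
mean would let one wavelength dominate. A raw mean is available via
`average_ppg_wavelengths(..., normalize=False)`.

## Cardio pipelines

Cleaning methods are zero-phase Butterworth designs addressed by id
(`nk_default`, `langevin`, `elgendi_ecg`, `none` for ECG; `langevin_ppg`,
`elgendi_ppg`, `nabian_ppg`, `none` for PPG). Two literal readings were
required where the literature description underdetermines the filter:

* `langevin` names a "notch" at a single 0.05 Hz cutoff; a true notch
  needs a center frequency and bandwidth, so the only well-defined reading
  of a single cutoff — a 0.05 Hz high-pass — is implemented.
* `nabian_ppg` names a single 40 Hz cutoff; implemented as a low-pass,
  valid at the 100 Hz PPG rate (Nyquist 50 Hz) and rejected with an
  explicit error at rates where 40 Hz meets Nyquist.
* `nk_default`'s 50 Hz powerline notch is applied only when the sampling
  rate exceeds 100 Hz; below that the mains region is unrepresentable.

Peak detectors (all enforcing a 250 ms refractory period, the 180 bpm
plausibility bound, keeping the larger peak of any too-close pair):

* `brammer` — QRS regions from the smoothed absolute gradient (20 ms
  pre-smoothing so sample-level noise does not dominate the gradient at
  1000 Hz), threshold at 40% of the 99th percentile, R peak = local max
  per region.
* `elgendi_dual_ma` — dual moving averages (event window 111 ms, beat
  window 667 ms, offset β = 0.08; values from the method's original
  description) over the squared band-passed signal. The band (8–20 Hz for
  ECG, 0.5–8 Hz for PPG) is applied inside the detector: the method is
  defined on band-passed energy, and internalizing it makes block location
  independent of the upstream cleaning choice.
* `nabian_window` — sliding-window local maxima; window = 2× the shortest
  plausible beat interval (180 bpm), with an amplitude gate halfway
  between the median and the 99th percentile.
* `gamboa` — local maxima of the min–max-normalized signal (prominence
  floor 0.05 to discard numeric ripple in flat baselines), gated at 0.8 ×
  the 80th percentile of candidate amplitudes. The literal 80th-percentile
  gate would drop most true beats whenever sampling jitter spreads their
  amplitudes around the percentile; the 0.8 factor separates R from T
  candidates (amplitude ratio ≈ 2) while tolerating that jitter.

Parameters: mean HR = 60000/mean(interval ms); SDNN = sample SD (ddof = 1)
of intervals; RMSSD = root mean square of successive differences. The
n−1 convention is used everywhere for consistency with the Bland-Altman
statistics.

## Signal quality index

10-s epochs, contiguous from run start, trailing partial epoch discarded;
a peak exactly on a boundary belongs to the later epoch. Rules: epoch HR
(= 60000/mean within-epoch interval — the "extrapolated HR" has no
published formula, this is the natural reading) within 30–180 bpm; max
peak gap ≤ 3 s; max/min interval ratio < 2.2; and mean Pearson
correlation of beat windows (width = median beat interval, forced odd,
centered on each peak, edge windows dropped) with their mean-beat
template ≥ 0.66 (ECG) / 0.86 (PPG). A zero-variance window scores r = 0,
counting against quality. The template is per-epoch by default; a
whole-run template variant is available (`template_scope="run"`) because
the literature describes both readings.

Intervals spanning an epoch boundary belong to the epoch of the later
peak. When good epochs are concatenated, a spanning interval survives
only if the preceding epoch is also good and kept — concatenating across
a rejected epoch would otherwise fabricate a giant interval and corrupt
RMSSD. The device with more good epochs drops trailing good epochs until
counts match ("trimmed to equal lengths"); dropping from the end is the
simplest deterministic reading.

## EDA pipelines

Cleaning: 4th-order Butterworth low-pass at 3 Hz (`nk3hz`) or 5 Hz
(`biosppy5hz`). Decomposition: `highpass005` (0.05 Hz high-pass = phasic,
tonic = signal − phasic) and `median4s` (tonic = 4-s rolling median with
reflect padding, phasic = residual) — both conserve tonic + phasic =
input exactly. The convex sparse-deconvolution decomposition (`cvx`)
requires a quadratic-program solver and raises `NotImplementedError` when
none is available rather than silently substituting another method; the
default pipelines do not depend on it.

SCR detectors: `nk_default` (first-derivative maxima above 10% of the
tallest interior derivative maximum — a 2-s edge margin keeps zero-phase
filter transients out of both the threshold and the candidates — with
rise-time validation 0.5–5 s), `kim` (20-*sample* Bartlett smoothing, kept
literal at 1.33 s for 15 Hz data; SCRs between −/+ and +/− zero
crossings, a rise without a later fall closes at the signal end), `gamboa`
(peak/onset pairing, nearest preceding minimum within 5 s, unpaired peaks
dropped), `nabian` (derivative zero-crossing pairs, rejecting amplitudes
below 10% of the maximum detected amplitude). Pipelines averaging more
than 30 SCR/min across runs on the reference device are excluded as
overestimating (plausible rates: 1–3/min at rest, ≤ ~25/min under high
arousal), as are pipelines with mean amplitude below 0.01 μS
("close-to-zero"; the cutoff is a package choice, no published value
exists).

## Agreement statistics

Limits of agreement: mean ± 1.96 × sample SD of per-run differences
(wearable − reference). The Bland-Altman ratio divides 1.96·SD by the
*magnitude* of the average pairwise mean, keeping BAr ≥ 0 even when the
mean level is negative (the signed ratio is exposed as `bar_signed`).
Categories: BAr < 0.01 excellent, 0.01–0.1 good (boundaries inclusive),
0.1–0.2 moderate, > 0.2 insufficient. HR, interval SD, RMSSD, SCL and SCR
amplitude are log10-transformed per device value before differencing;
SCR rate is not transformed by default (configurable), since rates of
zero are legitimate and the published treatment of this parameter is
ambiguous. Plausibility bands (±5 bpm for mean HR; others config entries)
annotate reports only and never gate data.

Cross-correlation: both series linearly detrended and z-scored, the
coefficient at lag k is Σ a[t]·b[t+k] / n over the truncated
(non-circular) overlap, so a series' lag-0 autocorrelation is exactly 1;
lags run −8…+8 samples (±0.53 s at 15 Hz); positive lag = second series
delayed.

Pipeline selection follows the smallest SD of per-run inter-device
differences (the most *consistent* difference marks the most robust
processing when a site-driven level offset is expected); ties break
lexicographically with a warning. The cardio grid is instead ranked by
mean good-epoch percentage, matching how the best cardio pipeline is
identified in practice.

## Synthetic data

What it emulates: shared beat timing with two sinusoidal variability
components (LF 0.1 Hz, HF 0.25 Hz) plus white jitter (closed-form
SDNN/RMSSD targets); a stylized QRS (narrow biphasic spike + T wave) and
a skewed gamma-like pulse lobe delayed by a 0.2 s pulse-transit time;
shared electrodermal ground truth (linear tonic drift + peak-normalized
Bateman kernels, default τ_rise 0.75 s / τ_decay 2 s) rendered through
per-device gain/offset/lag/drift/noise; and injectable artifacts
(flatline, burst noise, beat deletion) to construct epochs the SQI must
reject. The Bateman kernel is peak-normalized so the configured amplitude
is the literal SCR amplitude, making amplitude-recovery tests exact.

Default study conditions: 180-s runs, base HR drawn from 55–85 bpm (+4 bpm
in the hard condition), SCR rate 2/min (+50% under load) with lognormal
amplitudes around 0.4 μS, palm tonic level 6–10 μS, and an arm-site EDA
device with gain 0.35 and offset −0.5 μS — a deliberately large
site-difference so the EDA agreement behaves qualitatively like real
palm-vs-arm comparisons (large level offset, preserved temporal
correlation).

What it does not emulate: P waves, ectopic beats, motion-artifact
physics, respiration coupling beyond the HF sinusoid, vascular waveform
variety, or electrode drift nonstationarity. Passing tests therefore
demonstrate algorithmic correctness (filters, detectors, rules, and
statistics do what their definitions say, and the full chain recovers
known ground truth), not field performance on real wearable data.

## Numerical choices and degenerate inputs

All filters are zero-phase (`sosfiltfilt`) and length-preserving; any
cutoff at or above Nyquist raises an error naming the method and rate.
Downsampling applies an 8th-order Butterworth anti-alias low-pass at 0.4 ×
the target rate before polyphase rational resampling (`padtype="line"`
for edge behavior). Flat signals yield empty peak lists, not errors.
Constant series make cross-correlation undefined (error), and a
zero-mean-level Bland-Altman ratio is an explicit error. All randomness
derives from explicit integer seeds via `numpy.random.default_rng` /
`SeedSequence`; simulate-mode reports are byte-identical given
(config, seed).

Problem sizes in the shipped tests and the acceptance script (runs of
60–180 s, 2–4 synthetic participants, 20-seed averages for monotonicity
properties) are chosen so the whole suite completes in well under a
minute while every statistic is still estimated on dozens of beats or
epochs per run.

## Known limitations

* The `cvx` decomposition is an interface without a bundled solver.
* CSV dialects are package-defined (wide/long + JSON sidecar); vendor
  binary formats and live streaming are out of scope — only shared-clock
  trimming is implemented for alignment.
* Frequency-domain HRV, ectopy handling, event-locked SCR analysis and
  regression-based bias modeling are deliberately not implemented.
* Study-level published agreement values depend on raw participant data
  that is not publicly available; the package reproduces the published
  worked arithmetic and validates the machinery on synthetic ground truth
  instead.
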