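# Methods

## Signal model and analysis chain

The gastric slow wave is treated as a narrow-band rhythm in 0.5–9.0 cpm
(0.008–0.15 Hz) riding on broadband interference (respiration, ECG, motion).
The chain is: anti-alias downsampling to a common 4 Hz analysis rate →
zero-phase band-pass extraction of the gastric band → per-segment artifact
screening → running spectral analysis (RSA) per segment → overall spectral
analysis (OSA) per period → the clinical parameter table. All amplitudes are
held in mV; file I/O converts to/from integer A/D counts via the header's
counts-per-mV scale and is bit-exact on counts.

### Filtering

Three zero-phase band-pass modes (default band 0.008–0.15 Hz):

- **butterworth** — 4th-order Butterworth band-pass run forward and reverse
  (`sosfiltfilt`), doubling the effective order and cancelling phase;
- **zero_phase_inverse_butterworth** — the complement scheme: output = input −
  zero-phase band-stop of the same edges. The magnitude response differs from
  the direct band-pass (flatter pass band, softer skirts) while keeping the
  zero-phase contract; the original "inverse Butterworth" design this mode
  stands in for is not publicly specified, so the complement construction is
  this package's own choice.
- **ib_dct** — index-blocked DCT: the whole-signal DCT-II coefficient k maps
  to frequency k·fs/(2N); coefficients outside the band are zeroed and the
  transform inverted. Exactly zero phase, but block-based (no streaming).

With a `low_hz` of 0 the designs degrade gracefully to low-pass. Filters are
implemented in second-order sections; at the 4 Hz analysis rate the normalized
edge frequencies are well-conditioned. For this reason the pipeline
deliberately extracts the EGG band *after* downsampling: a 0.008 Hz edge at
200 Hz sampling (normalized ~8·10⁻⁵) is numerically fragile even in SOS form,
and since both stages are zero-phase LTI operations the band content is
unchanged by the reordering.

Anti-aliasing before decimation is a zero-phase 4th-order low-pass at 2.0 Hz;
integer ratios decimate directly, non-integer ratios (e.g. 250 Hz) use
polyphase rational resampling.

### Artifact screening

Both methods tile the signal into non-overlapping segments (defaulting to the
RSA segment length so exclusions align with analysis segments), compute each
segment's sample SD, and set the limit to threshold × mean SD. Method 1
(threshold 4.2) flags a segment when **any** absolute sample exceeds the
limit; Method 2 (threshold 1.6) flags it when the **segment SD** exceeds the
limit. Comparisons are strict (`>`), which makes the all-zero signal
well-defined (nothing flagged). Flags are OR-ed across channels — an artifact
anywhere excludes the segment everywhere — and manual intervals (in minutes,
closed endpoints) are added on top. SD statistics are computed on the
band-passed EGG, since screening follows extraction in the workflow.

### Running spectrum analysis

Segments of `lseg_s` (default 240 s) advance by `lseg_s − sseg_s`
(default 120 s); trailing partial segments are dropped. Estimators on a
`lspv`-point grid (default 4096) over [0, fs/2]:

- **Periodogram**: demeaned segment × window (Tukey α = 0.25 default,
  Barthann, Hann), zero-padded to nfft = 2(lspv−1), scaled by 1/(fs·Σw²)
  (one-sided), so white noise has window-independent mean level. PSDs are
  reported in mV²/cpm on a cpm grid.
- **AR (Burg)**: a hand-written Burg lattice recursion returns the reflection
  coefficients and driving variance for *all* orders up to 30 in one pass;
  the order is argmin over 1..30 of AIC(p) = N·ln σ²ₚ + 2p, **plus a fixed
  +6** that sharpens spectral detail. The spectrum is 2σ²/(fs·|A(f)|²).
  Burg's |k| ≤ 1 guarantees stable models; a constant segment falls back to
  order 1+6. The AIC uses σ² normalized by N throughout; other normalizations
  shift the argmin on flat AIC valleys, which is why the test-suite oracle
  re-derives σ² with the same convention while the *coefficients* are
  cross-checked against an independent implementation (statsmodels).

**Dominant peak.** DF is the frequency of the global PSD maximum when that
lies in 0.5–9.0 cpm (ties break to the lower frequency; the dB reference is
1 mV²/cpm — only differences are meaningful). When the global maximum falls
below 0.5 cpm (DC lobe), the largest *other* local maximum above 0.25 cpm is
examined: it becomes the corrected DF only if it is in band and less than
2.5 dB below the raw maximum; otherwise — as when the global maximum lies
above 9 cpm — the segment is arrhythmic. The 0.25 cpm floor excludes shoulder
maxima of the DC lobe itself. Rhythm classes: DF < 2 cpm bradygastria,
2–4 cpm (inclusive) normogastria, > 4 cpm tachygastria; no DF → arrhythmia.

### Overall spectrum analysis

Periods come from the header meal times: pre-prandial [0, meal start), the
meal itself, then consecutive 30-minute postprandial periods (a trailing
partial period is kept if it holds at least one segment). Meal times (0, 0)
mean a single period. Segment grids restart at each period start; artifact
segments are dropped; linear PSDs are averaged pointwise; ODF/ODP use the
same dominant-peak rule as RSA. The meal period is excluded from averaging
and from the whole-exam spectrum by default (`include_meal` overrides) —
chewing and movement make it unusable in practice. Band power percentages
integrate the linear PSD by the trapezoidal rule with interpolated band
edges over [0.5, 2), [2, 4], (4, 9] cpm, normalized by the 0.5–9 cpm total.
A MUSIC pseudospectrum (signal-subspace dimension 2 × 2 expected sinusoids,
correlation dimension 64) is available as a peak locator; its amplitudes are
not power densities, so its ODP/band powers are indicative only.

### Clinical parameters

Computed over included segments per period and whole exam (meal excluded from
"whole" by default): rhythm percentages (denominator = included segments;
arrhythmic segments count here but not in DF/DP statistics), DF/DP
mean/median/sample-std (ddof = 1; n = 1 → 0 by convention), FIC/PIC as
coefficients of variation — PIC on linear power 10^(DP/10) by default, which
is invariant to the dB reference (a `db` scale is available for comparability
with commercial systems) — max DF difference, slow-wave coupling (segments
paired by start time, % with |ΔDF| ≤ 0.2 cpm, the tolerance used in the
clinical literature; symmetric by construction), spatial DP difference
(max − min of per-channel mean DP), and the fed/fast ratio
10^((ODP_post − ODP_pre)/10) from the OSA overall dominant powers.

### HRV

Pan-Tompkins detection: 5–15 Hz zero-phase band-pass, derivative, squaring,
150 ms moving-window integration, adaptive signal/noise threshold estimates
(0.125/0.875 running updates), 200 ms refractory distance, search-back at
half threshold when 1.66× the running mean RR elapses without a beat, and
refinement of each detection to the local extremum of the band-passed ECG.
RR intervals (ms) are anchored at their closing R peak and cubic-spline
interpolated onto a 4 Hz grid spanning first to last R time (the spline
extrapolates smoothly across the first interval). Time-domain indices follow
the literal formulas; pNN50 divides NN50 by the *total number of RR
intervals*. Frequency-domain analysis detrends (linear) and Hann-windows each
256 s window (128 s overlap), integrates VLF 0.003–0.04, LF 0.04–0.15 and
HF 0.15–0.40 Hz trapezoidally, normalizes relative powers by
total = VLF + LF + HF, and reports aggregate values as means over windows —
the configuration used by standard HRV packages this pipeline was designed to
be comparable with.

## Synthetic worlds

`gen_egg` emulates the validation recordings: per channel
A·sin(2π·f·t + φ_ch) plus white Gaussian noise with variance (A²/2)/10^(SNR/10),
90 min at 200 Hz, mid-tread-quantized to 12 bits with a counts-per-mV scale
chosen so the span uses ≤ 90 % of the A/D range. Defaults: 3 cpm, 200 µV
(mid physiological range; the validation conditions fix frequency, SNR,
duration, rate and bit depth but not amplitude), zero phases (perfectly
coupled channels — SWC 100 % by construction), a pink-noise option for
robustness work. What it does *not* emulate: respiratory/ECG interference,
nonstationary frequency drift, electrode pops, or real meal responses — a
green test on this world establishes estimator correctness, not clinical
performance on human data. `inject_artifacts` adds rectangular gain bursts
for screening tests; `gen_ecg_rr` builds an ECG-like train (Gaussian QRS
template) whose RR follows 60000/HR + Σ depth·sin(2πft) ms and returns the
exact template centers, giving ground truth for detector timing.

## Numerical choices and limitations

- Spectral grid: lspv points over [0, fs/2] (bin ≈ 0.029 cpm at defaults);
  peak locations are reported on-grid, no interpolation.
- Strict inequalities at artifact limits; closed intervals for manual marks;
  ties at spectral maxima go to the lower frequency.
- PSD floor 10⁻³⁰⁰ before log for dB views of zero bins.
- The AR spectrum of heavily band-limited input can place its global maximum
  outside the gastric band; such segments fall to the correction rule or are
  classed arrhythmic rather than being silently clipped into band.
- No ectopic-beat correction is applied to RR series; HRV indices assume the
  detected beats are sinus beats.
- Period statistics assign a segment to the period containing its start time;
  segments straddling a period boundary are not split.
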