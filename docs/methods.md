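# Methods

This note records the models, conventions and numerical choices behind
`hfoscan`, including the places where the design was genuinely open and
what the synthetic validation does and does not demonstrate.

## Recording model and units

Recordings are signed 16-bit ADC counts d_i ∈ [−2¹⁵, 2¹⁵−1] at a
sampling rate of ~12207 Hz, one flat little-endian binary file per
channel per block (endianness is not dictated by any acquisition
standard; little-endian is the common PC convention and is
config-overridable). Durations given in seconds convert to sample
counts by rounding half away from zero, with one deliberate exception:
the EMD boundary buffer uses the floor (0.5 s → 6103 samples at
12207 Hz), matching the segment arithmetic used throughout.

## Quality control

σ_s is the standard deviation (1/(2N−1) normalization) of the
successive differences s_k of the per-value count histogram n_j. Two
closed forms anchor the implementation: a uniform histogram gives
σ_s = 0, and an all-zero file of length L gives σ_s = L·√(2/(2N−1))
(≈ 5524.4 for L = 10⁶).

σ_s grows with file length L, but the growth law depends on the
histogram's shape. When the smooth shape of n_j dominates its
bin-to-bin differences (narrow histograms relative to the 2¹⁶-value
range — the situation for real EEG at ~3·10⁸ samples), σ_s ∝ L. For
wide histograms at desk-scale L, the i.i.d. multinomial counting noise
dominates and σ_s ∝ √L instead. The linear-scaling property test
therefore uses a narrow synthetic distribution (σ_ADC = 5), which is
the regime the field-length argument describes.

Classification bands are configuration, not constants: the published
bands (normal 10²–10³, corrupted 10⁴–10⁵) correspond to ~3·10⁸-sample
files and must be rescaled for shorter files. σ_s values falling
between bands default to `normal` with a warning flag, because
near-seizure files legitimately spill above the good band; a
zero-fraction cut (n₀/L > 0.01 → `zeros`) supplements σ_s because short
zero runs need not dominate it.

## EMD

Sifting interpolates strict local maxima/minima with cubic splines
(plateaus count once, at the floor-midpoint index), subtracts the
envelope mean, and stops on the Rilling amplitude-ratio criterion
(θ₁ = 0.05, θ₂ = 0.5, tolerance 0.05) **and** the IMF condition
|#extrema − #zero-crossings| ≤ 1. The iteration cap is 300: one mode of
a long noise segment occasionally needs ~200 sifts to clear the IMF
condition, while typical modes converge in well under 20. Envelope ends
are stabilized by mirroring the two nearest extrema across each segment
end. Decomposition stops when the remainder has fewer than two maxima
or two minima (monotonic residual), with a cap of 16 modes.

Long files are decomposed in 5 s segments extended by 0.5 s boundary
buffers on each side; only core-segment IMF samples are kept, which
confines spline edge effects to discarded data and makes each segment's
result independent of content beyond its buffers.

**Guard tones.** Before decomposition a bank of sinusoids (0.9, 0.5,
0.25, 0.125, 0.0625, 0.03 at 100, 200, 500, 1000, 2000, 5000 Hz;
triangle-inequality bound 1.8675 ADC counts, ~10⁻³ of normal signal
amplitude) is added, phase-continuous in the absolute sample index.
Across zero-filled blocks they supply the extrema the spline fit needs.
Validation on a 0.4 s zero block inside strong noise: the modes above
the highest guard frequency stay at guard-tone scale inside the block
(≤ ~0.1 counts vs spurious swings of 10³–10⁴ without injection, a
≥10⁵× suppression); modes at and below the bank's band keep a residual
skirt near the block edges of a few mode periods, still suppressed
≥100×. On clean data the tones are invisible downstream.

Noise-mode handling: at 12207 Hz the first three modes are
noise-dominated (~1.4–5 kHz). Rather than skipping a fixed count, the
detector gates IMFs by mean frequency (zero-crossing rate), see below.

Instantaneous frequency is available per sample (analytic signal with
zeroed negative frequencies; phase-derivative, 5-sample median smooth)
and per period (intervals between neighbouring maxima, supporting a
time-varying period track T(t)).

## Detection

The amplitude function integrates |IMF| (trapezoid rule) over a sliding
window of w = 7 periods, stepping one period; window anchors are the
span centres, and each window's full support is kept because anchor
times understate an event's physical extent by one window width. The
threshold A_c = a_μ·μ + a_σ·σ uses population moments of a reference
stretch (default 1 h; shorter data are used whole and flagged).
Defaults a_μ = 1, a_σ = 2.5: with a_σ = 1 the amplitude stream of a
desk-scale file is flooded with noise on-intervals; 2.5 was validated
on the planted benchmark (below). Supra-threshold runs must span ≥2
amplitude samples (a single point has zero duration and zero on-area by
the trapezoid rule, and would violate the interval invariant
end > start).

**Outlier selection and its limits.** On-intervals are sorted by
descending on-area and accepted greedily while
S₁ > α·E[{Sᵢ}ᵢ≥₂] + β·Var[{Sᵢ}ᵢ≥₂] (population variance; Var := 0 with
one remaining interval; no selection with fewer than three intervals;
α = β = 1). This score adds quantities with units of S and S², so its
stopping point depends on the absolute on-area scale: when the variance
term is negligible the greedy accepts nearly every interval of a
continuous sample (the largest remaining value always exceeds the
remainder mean), and when it dominates it rejects even the head.
Because of this, selection alone cannot control false positives, and
the detector adds a dimensionless veto: a selected interval is kept
only if its mean supra-threshold excess S/(T·σ_A) exceeds
`min_excess` = 2.5 amplitude standard deviations. Marginal noise
excursions above an empirically estimated μ+3σ threshold rarely sustain
2 σ_A; genuine transients at ≥5× background amplitude run 3–8 σ_A.

Accepted events with gap G < g·min(T₁, T₂) merge (g = 0.5; iterated to
a fixpoint), frequencies are f = n/T_HFO with n the count of intervals
between neighbouring maxima inside the event, and bands are
population spike (<80 Hz), ripple (80–200 Hz), fast ripple (>200 Hz).
(The introduction-level convention of 100–200 Hz ripples differs from
the detection-level 80 Hz cut; the detection convention is
implemented.) Overlapping detections from different IMFs combine into
their union span.

Two refinements address EMD mode mixing, which lets a strong transient
surface partly in the mode above its nominal band with a distorted
local extrema rate:

* the IMF scan gate defaults to mean frequency ∈ [10, 900] Hz — the top
  reaches one mode above the fast-ripple band because ~20% of planted
  250–350 Hz events otherwise went undetected;
* after merging, each event's period count is re-estimated from the
  dominant spectral peak of the raw signal restricted to the scan band
  over the event span, and re-quantized so f = n/T_HFO holds exactly.
  Per-IMF extrema counting remains available (`estimate_frequency`) but
  misjudged the band of events split across two modes.

**Benchmark.** The standard validation plants 20 non-overlapping events
(8 ripples 120–180 Hz, 6 fast ripples 250–350 Hz, 6 population spikes
30–50 Hz; durations 50–200 ms; Gaussian envelope with σ = duration/6;
peak amplitude 5–8× the background σ of 100 counts) in 60 s of white
Gaussian background at 12207 Hz. Over eight seeds: recall 0.90–1.00,
precision 1.00, band accuracy 100%. A background-only control (10 s at
2000 Hz, a_σ = 3, twenty seeds) yields zero detections in 19/20 runs.
These numbers characterize the detector under white-background
conditions with well-separated, high-SNR events; real EEG adds 1/f
background, artifacts, and overlapping events of graded SNR, so they
are upper bounds on field performance, not predictions.

## Scaling analysis

Per-segment thresholds come from the normalized amplitude distribution
(histogram rescaled to peak 1, 200 bins): A_c is the first point past
the peak where P drops to the chosen level p, linearly interpolated
between bin centres. Duration densities are log-binned (10 bins per
decade, occupied-bin mass normalized to 1).

Exponent estimators:

* `mle` — closed form α̂ = 1 + n/Σln(Tᵢ/T_lo) above a lower bound;
  goodness is 1 − KS distance against the fitted Pareto. Bias ≲0.015 at
  n = 10⁵ for γ ∈ [2.5, 5.5].
* `loglog_ls` — least squares on the log-binned log-log density
  (requires ≥5 occupied bins); goodness r². Mirrors the visual
  convention of scaling plots but inherits histogram-binning bias; the
  MLE is the default for quantitative work.

The default fit range for direct calls is [5th, 99th] percentile.
`segment_scaling_report` instead uses `fit_range="auto"`, a
Clauset-style scan that picks T_lo by KS minimization: quantile
thresholds sit only ~1.5–3 σ above the off-baseline of an intermittent
amplitude process, so noise excursions create short spurious intervals
below the scaling regime that destroy a fixed-range fit at p ≥ 0.2
(γ̂ collapses toward 1.4); with the auto bound, γ̂ is stable to ~0.05
across p ∈ [0.02, 0.3].

The end-to-end validation builds an on–off amplitude process directly:
power-law on durations (γ, T ∈ [0.1, 10] s), exponential off durations
(mean 0.3 s), baseline 10 ± 2 and burst 50 ± 5 amplitude units on a
5 ms grid, with noise smoothed over 7 samples to mirror the heavy
autocorrelation of real amplitude functions (neighbouring windows share
all but one period). Thresholding this process at quantile levels and
fitting recovers γ within 0.05–0.3 and orders two segments generated
with different exponents correctly. This demonstrates the estimation
machinery; published rat-specific exponents are not reproducible
because the underlying recordings are not deposited.

## Synthetic data: what it does and does not emulate

The generator provides: white Gaussian background (optional 1/f
shaping, since no background spectrum is prescribed for this kind of
recording; optional sinusoidal amplitude modulation emulating circadian
rhythm), windowed-sinusoid events (Gaussian or Tukey envelope),
zero-block corruption (union semantics), repeated-template corruption,
truncation, int16 quantization (round half away from zero, saturation
counted in the sidecar), and per-file seed streams derived from one
master seed via counter spawn keys so any file regenerates in
isolation. It does not emulate spatial correlation across channels,
seizure morphology, electrode drift, or physiologically realistic
spectra; conclusions from passing tests are about the algorithms, not
about clinical performance.

## Known limitations

* The outlier-selection score is scale-sensitive (units of S vs S²);
  specificity rests on the amplitude threshold and the excess veto.
* EMD mode mixing on sharp transients is mitigated, not eliminated; the
  spectral refinement assumes one dominant oscillation per event span.
* IMF rows are stacked across segments by index; on strongly
  non-stationary data a mode's band can drift between segments.
* Boundary-buffer suppression of edge artifacts leaves a skirt of a few
  mode periods around zero-blocks in the low-frequency modes.
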