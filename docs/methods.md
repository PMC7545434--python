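# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `evokedlfp`, and what the synthetic testbed does and does
not establish about real recordings.

## Signal model and synthetic recordings

A simulated recording is the sum of four components, on a common time grid
of `sampling_rate` Hz (default 16 000 Hz, the emulated acquisition rate;
analyses in the test suite run at 1 000 Hz, which preserves every band of
interest below 100 Hz — see *Problem sizes*):

1. **1/f background.** Gaussian white noise spectrally shaped to a
   1/f^α power spectrum (default exponent α = 1.0), scaled to `noise_sd`
   (default 20 µV, a plausible ongoing-LFP scale; free choice). Shaping is
   done by multiplying the rFFT of white noise by f^(−α/2) and inverting.
2. **Spontaneous bursts.** A Poisson process (default 0.05 events/s — one
   burst every ~20 s, in the range seen under light anesthesia; free
   choice) of 300-ms band-limited bursts in a random canonical band with
   envelope gain drawn uniformly from 2–4. These exist so the baseline-bin
   selection rule has something to avoid.
3. **Evoked potential.** A deterministic damped sinusoid
   exp(−t/τ)·sin(2πf₀t) starting `ep_latency_ms` (20 ms) after each
   stimulus, with f₀ = 20 Hz and τ = 30 ms, *normalized so its sampled peak
   equals `ep_amplitude` exactly* (default 200 µV). Any smooth biphasic
   waveform with an unambiguous peak would serve; the normalization makes
   "amplitude" mean what the feature extractor measures.
4. **Induced bursts.** Per stimulus and per `BurstSpec` whose condition
   mask contains the recording's condition: band-limited Gaussian noise
   under a raised-cosine (Hann) window. Because the carrier is fresh noise
   on every trial, these bursts are not phase-locked: they cancel in the
   across-trial average but appear in single-trial energy — the phenomenon
   the frequency-domain analysis exists to detect.

**Burst amplitude semantics.** No amplitude scale for induced activity
relative to background was available, so the gain parameter is defined
operationally: a burst with `amplitude_gain` g is scaled so that the mean
band energy over its window is ≈ g² × the background's band energy
(burst RMS = √(g²−1) × background band RMS; the Hann window's mean-square
of 3/8 is compensated; noise and burst add incoherently). g = 1 means no
burst; the measured normalized energy is monotone in g. When the
background is absent (noise_sd = 0) the reference scale falls back to
1 µV.

An acquisition-style zero-phase 4th-order Butterworth low-pass at 100 Hz
is applied to the stochastic components (background + bursts). The EP is
added *after* this filter: its spectral content sits far below the corner,
and adding it unfiltered keeps an exact invariant — with all stochastic
sources disabled, the trace equals the analytic sum of EP waveforms sample
by sample — that the tests exploit.

**Cohorts.** `simulate_cohort` derives per-subject seeds deterministically
from each age group's master seed and draws one lognormal EP-amplitude
multiplier per subject (σ = 0.15, a modest inter-animal variability; free
choice) shared across that subject's conditions, so the paired design is
preserved. Age groups are nothing but parameter sets (which bursts exist);
no developmental model is implied. Conditions (`A`, `AC`, `AC_preQX`,
`AC_postQX`, extensible via burst masks) differ only in which induced
bursts are present; C-fiber silencing is modeled as the removal of the
C-fiber-attributed bursts, nothing more.

## Epoching and evoked-potential features

Epoch windows are half-open `[stim − pre, stim + post)` with 0-based
indexing; the sample at t = 0 is the first post-stimulus sample. EP
analysis uses 1.5-s epochs (0.15 s pre, 1.35 s post); energy analysis uses
10-s epochs (5 s pre, 5 s post) so the 1.5-s analysis span is far from
filter edges. Averaging subtracts each epoch's pre-stimulus mean first, so
features are invariant to constant offsets.

The peak is the largest absolute deflection in a configurable search
window (default 0–300 ms); magnitude and polarity are reported separately
since the sign convention of "peak amplitude" is ambiguous in the field.
Onset is the first post-stimulus time where |signal| exceeds
`onset_k` × (pre-stimulus SD) — the standard deviation-threshold
convention, default k = 3 — and stays above threshold for ≥ 3 ms; absent
crossings yield a missing value (never 0) plus a `no_onset` flag. The
first 2 ms post-stimulus are blanked as stimulus artifact (configurable).

## Band energy and normalization

Filters are zero-phase forward–backward (`sosfiltfilt`) Butterworth
band-passes of order 4 per pass — zero phase so envelope latencies are not
displaced; the effective attenuation one octave outside the band exceeds
40 dB. Padding is ~3 cycles of the low band edge so narrow-band
transients settle. Instantaneous energy is |analytic signal|², which for
A(t)·sin(2πft) tracks A(t)² away from edges (verified to 2% against the
closed form). Post-stimulus bins (0–500, 500–1000, 1000–1500 ms,
half-open) are arithmetic means of the energy series.

**Baseline.** Candidate 500-ms pre-stimulus bins tile backwards from the
stimulus, staying 250 ms clear of the epoch edge. Scanning from the latest
backwards, the first bin whose mean energy is ≤ 2× the median of all
candidates is taken (`clean`); if none qualifies, the minimum-energy bin
is used and flagged `forced`. This operationalizes "a baseline bin that
does not include a spontaneous burst".

**Normalization order.** By default (`normalization="pooled"`) the energy
series is first averaged across a subject's stimulus repetitions, the
baseline bin is chosen on that averaged series, and the post-stimulus bin
means are divided by the baseline mean. The alternative
(`normalization="per_epoch"`) divides every epoch by its own baseline bin
and averages the ratios. Pooled is the default for two reasons: it matches
the procedure's natural reading (average across repetitions, then
normalize), and it is the statistically sane choice — a single 500-ms
baseline bin holds only ~B·T ≈ 1 independent envelope samples in the δ
band, so E[1/baseline] diverges from 1/E[baseline] and the per-epoch ratio
is strongly biased upward in narrow bands (measured ≈ 2.6× for δ on
stationary noise, versus ≈ 1.02–1.09 pooled). Even pooled, a small
positive bias (≲ 9% in δ/θ, ≲ 1% broadband) remains; it is inherent to
ratio-to-a-noisy-baseline estimators and is condition-symmetric, so paired
contrasts are unaffected.

"Total" energy is a 2–90 Hz broadband pass, not the sum of the five bands
(the canonical bands leave gaps at 4–5, 7–8 and 12–15 Hz, which are kept
verbatim; no interpolation). Scale invariance holds exactly: multiplying a
recording by any constant leaves every normalized-energy cell unchanged.

## Estimation statistics

- **Effect size**: paired mean difference, positive ⇒ second condition
  larger.
- **BCa interval** (default 5000 resamples, level 0.95): pairs are
  resampled with replacement; bias correction z₀ = Φ⁻¹(fraction of
  resampled estimates below the point estimate), acceleration from the
  jackknife third-moment formula a = Σu³ / 6(Σu²)^{3/2}. Degenerate data
  (all differences equal d) return [d, d]; zero jackknife variance is
  treated as a = 0; the z₀ proportion is clamped to (0, 1) to avoid
  infinite quantiles. Implementation cross-checked against
  `scipy.stats.bootstrap(method="BCa")` in the tests.
- **Permutation p** (default 5000 reshuffles): the two condition labels
  are exchanged independently within each pair — equivalently each paired
  difference's sign is flipped — because pooling labels across subjects
  would break the pairing. The statistic is |mean difference| (two-sided
  by construction, not a doubled one-sided tail);
  p = (1 + #{null ≥ observed}) / (1 + N) so finite resampling never
  reports p = 0. `mode="exact"` enumerates all 2ⁿ sign patterns (n ≤ 20)
  and returns the exact tail fraction; tie comparison uses a relative
  1e-12 tolerance. With n = 6 pairs the attainable two-sided levels are
  multiples of 1/64, so the smallest possible p is ≈ 0.031 and the true
  type-I rate at α = 0.05 is ≈ 0.031, not 0.05.
- **ANOVA**: the two-way mixed (within condition × between age) and fully
  repeated-measures designs are delegated to `pingouin` (a standard
  computation, verified in the tests against explicit sums-of-squares
  arithmetic); an all-constant response is reported as F = 0, p = 1 rather
  than NaN. Post hoc paired comparisons use `scipy` paired t-tests with
  the exact Sidak correction 1 − (1 − p)^m; Tukey's HSD is deliberately
  approximated this way and documented as such.

All resampling is seeded; pipeline strata derive their seeds from the
master seed plus the stratum labels (CRC32 of contrast/age/band names), so
results are independent of evaluation order and identical config + seed
gives byte-identical CSV outputs.

## What the simulator does and does not establish

The generator reproduces the *statistical structure* the analysis assumes:
1/f background, phase-locked EPs, non-phase-locked induced bursts with
condition-dependent presence, spontaneous bursts, paired subjects. Passing
tests therefore demonstrate that the chain recovers known injected effects
at realistic sizes and calibrates correctly under the null. They do not
validate: volume-conduction or electrode physics, non-stationary
anesthesia depth, line noise or movement artifacts, inter-subject spectral
variability beyond EP-amplitude jitter, or any biological claim about
fiber recruitment — on real data those factors can degrade sensitivity in
ways the simulation cannot reveal.

## Problem sizes and runtime choices

Simulation-heavy tests and the acceptance script run the generator at
1 000 Hz (the band content of interest ends at 90 Hz and the acquisition
model low-passes at 100 Hz, so nothing above 500 Hz Nyquist matters;
16 kHz remains the default for fidelity to the emulated acquisition).
Cohort-level checks use 6 subjects × 2 conditions × 10 stimuli, 50 seeded
runs for effect-recovery rates, 40 runs for null-energy calibration,
1000/500 replicates for permutation type-I error and 300–500 × 2000
bootstraps for BCa coverage. The envelope calibration uses a 60-s tone so
even the δ band (≈2.8 Hz center) contains dozens of cycles; shorter tones
are dominated by Hilbert edge leakage.

## Known limitations

- Narrow-band normalized energies are noisy at the 500-ms bin width
  (δ: ~1 independent envelope sample per bin); single-subject cells
  scatter ±0.3–0.4 around 1 under the null, and the ratio estimator keeps
  a small positive bias. Contrasts inherit only the variance, not the
  bias.
- The BCa interval is mildly anti-conservative below ~15 pairs; at n = 6
  the permutation p is the more trustworthy of the two inferences.
- Exact permutation enumeration is capped at n = 20 pairs.
- Single-channel only; no artifact rejection beyond the stimulus blank;
  no wavelet/multitaper spectrograms, phase-locking or coherence measures.
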