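# evokedlfp

Analysis of stimulus-evoked local field potentials (LFPs) from somatosensory
cortex: time-domain evoked-potential features, band-limited Hilbert-envelope
energy changes relative to baseline, paired condition contrasts, and
resampling-based estimation statistics — together with a synthetic LFP
generator so the entire chain runs end-to-end without any recorded data.

## The scientific problem

Electrical skin stimulation at intensities that recruit only fast myelinated
afferents ("A-fiber" stimulation) or additionally slow unmyelinated
nociceptive afferents ("A+C-fiber" stimulation) can evoke cortical responses
that look identical in the averaged evoked potential (EP) yet differ in
their *induced* oscillatory content — activity that is not phase-locked to
the stimulus and therefore cancels in the time-domain average but survives
single-trial energy analysis. The same logic applies to pharmacological
silencing of C fibers: activity attributable to C-fiber input should vanish
when those fibers are blocked.

The package quantifies this as follows. Continuous recordings with stimulus
times are segmented into epochs; for each frequency band
(δ 2–4, θ 5–7, α 8–12, β 15–29, γ 30–90 Hz, plus a 2–90 Hz "total" pass)
the epoch is band-pass filtered (zero-phase Butterworth) and its
instantaneous energy computed as the squared magnitude of the analytic
signal, |𝓗x(t)|². Energy is averaged within post-stimulus bins (0–500,
500–1000, 1000–1500 ms), averaged across the stimulus repetitions of one
subject, and divided by a pre-stimulus baseline bin chosen to avoid
spontaneous bursts — giving a unitless *normalized energy change* that is
1 for a stationary signal.

Within-subject condition contrasts (A+C vs A; after vs before silencing)
are then summarized with estimation statistics: the paired mean difference
Δ̄ = mean(x_b − x_a), a 95% bias-corrected-and-accelerated (BCa) bootstrap
confidence interval over resampled pairs (5000 resamples), and a two-sided
permutation p-value from sign-flips of the paired differences
(5000 reshuffles, p = (1 + #{|Δ̄*| ≥ |Δ̄|}) / (1 + N)). A two-way
mixed/repeated-measures ANOVA with Sidak-corrected post hoc comparisons is
available for EP features and total-energy tables.

Intended users: electrophysiologists analyzing stimulus-evoked LFP/EEG
energy, and methodologists who need a seeded, fully synthetic testbed for
paired estimation statistics on band-energy measures.

## Worked example

The bundled `p30-demo` scenario simulates a young-adult-like cohort of six
subjects recorded under both A-fiber-only ("A") and A+C-fiber ("AC")
stimulation (10 stimuli, 10-s interval). C-fiber-attributed γ, β and α
bursts appear 500–1000 ms post-stimulus only under "AC".

```python
from evokedlfp import RunConfig, run_pipeline

cfg = RunConfig(scenario="p30-demo", sampling_rate=1000.0, seed=3,
                n_boot=1000, n_perm=1000)
res = run_pipeline(cfg, "demo_run")
mid = res.contrasts[res.contrasts.bin_start_ms == 500.0]
print(mid[["band", "mean_diff", "ci_low", "ci_high", "p_perm"]].round(3))
```

prints the AC-vs-A paired contrast in the 500–1000 ms bin:

```
 band  mean_diff  ci_low  ci_high  p_perm
alpha      1.779   1.386    2.392   0.024
 beta      5.015   4.395    5.989   0.025
delta     -0.139  -0.562    0.274   0.584
gamma      6.665   6.139    7.134   0.025
theta     -0.112  -0.594    0.417   0.715
total      2.814   2.529    3.149   0.029
```

Read: recruiting C fibers raised γ-band energy in that window by 6.7
baseline units (a subject's γ energy was ~7.7× baseline under AC vs ~1×
under A), with β and α also elevated, while δ/θ — which carry no injected
C-fiber activity — sit at zero difference with large p. With six pairs the
smallest attainable sign-flip p is 2/64 ≈ 0.031, so p ≈ 0.025 (with the
+1 correction) means the observed difference beat every non-trivial
relabeling. The same run writes `ep_features.csv`; the simulated EPs are
deliberately condition-independent:

```
subject_id age_group condition  peak_amplitude_uV  onset_latency_ms
   P30-s01       P30         A              257.8              21.0
   P30-s01       P30        AC              257.7              21.0
```

The same analysis is available from the shell:

```bash
evokedlfp simulate --scenario p30-demo --out recs/ --seed 3
evokedlfp analyze --config run.yaml --out run/ --seed 3
evokedlfp report --run run/
```

Recordings live on disk as `<name>.csv` (one `uV` column) plus a
`<name>.json` sidecar with sampling rate, stimulus times and metadata;
the pair round-trips losslessly.

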