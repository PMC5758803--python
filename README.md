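# echotune

Analysis of **omitted-stimulus ("echo") responses** in calcium-imaging data
from auditory cortex, with a calibrated synthetic forward model for
end-to-end validation.

When layer-2/3 neurons of the primary auditory cortex (A1) are driven by a
rhythmic pure-tone train (e.g. 20 tones at a 2-s inter-stimulus interval),
a subpopulation keeps responding *after the sound stops* — Ca²⁺ transients
appear at the anticipated times `t_end + k·ISI` (k = 1..5) as if the rhythm
continued.  These echo responses are smaller and later than sound-evoked
responses, occur preferentially when the train's frequency is close to the
neuron's best frequency (BF), and are spatially intermixed at the
~200 µm scale.  `echotune` implements the full analysis chain needed to
quantify this phenomenon from ROI fluorescence traces:

1. **Signal processing** — Δf/f with a 25th-percentile single-trial
   baseline, f0 = P₂₅(f), Δf/f = (f − f0)/f0; transient detection by peak
   amplitude (3 × noise SD), prominence, duration and rise-rate thresholds.
2. **Response analysis** — sound / echo / baseline measurement windows;
   per-neuron echo classification against a Poisson spontaneous-activity
   null (mid-P test at α = 0.05, empirical-Bayes per-neuron rates);
   amplitude and latency summaries.
3. **Frequency tuning** — 500-ms response integrals per tone, Gaussian fits
   `a·exp(−(x−μ)²/2σ²)+c` on x = log₂(f/1 kHz), BF = 2^μ kHz, and the
   ΔFrequency distribution log₂(f_echo / BF) in octaves.
4. **Population statistics** — per-session echo fractions (mean ± SEM
   across sessions), pooled amplitudes/latencies, Wilcoxon signed-rank and
   rank-sum comparisons, and a permutation test for local tonotopic
   structure of the echo-frequency map.
5. **Synthetic data** — a seeded forward model (double-exponential
   transient kernels, Gaussian log-frequency tuning, Poisson spontaneous
   events, 1–5 echo events at anticipated times in 15.7 % of neurons) whose
   defaults are calibrated so the default pipeline recovers the reference
   population statistics; every kernel is logged as ground truth, so each
   analysis stage is tested by parameter recovery.

It is aimed at systems-neuroscience practitioners who want a tested,
scriptable reference implementation of this analysis, or a harness for
benchmarking their own detectors/classifiers against known ground truth.

## Worked example

```python
from echotune import analyze_population, analyze_session, synthesize_session

bundle = synthesize_session(n_neurons=100, seed=1)           # one synthetic session
result = analyze_session(bundle.traces, bundle.protocol)     # full pipeline
pop, _ = analyze_population([result])

print(f"echo neurons: {result.echo_fraction_pct:.1f} %")
print(f"sound amplitude: {pop.amp_sound_mean:.3f} df/f   echo: {pop.amp_echo_mean:.3f}   baseline: {pop.amp_baseline_mean:.3f}")
print(f"sound latency: {pop.lat_sound_mean:.3f} s   echo latency: {pop.lat_echo_mean:.3f} s")
print(f"p(echo vs baseline) = {pop.p_amp_echo_vs_baseline:.2e}")
```

prints

```
echo neurons: 19.0 %
sound amplitude: 0.083 df/f   echo: 0.050   baseline: 0.014
sound latency: 0.085 s   echo latency: 0.239 s
p(echo vs baseline) = 3.81e-06
```

Reading the numbers: 19 of 100 neurons in this single session are
classified as echo neurons (the per-session fraction is binomially noisy
around the generated 15.7 %; averaging 8 sessions recovers it).  Pooled
sound-evoked peak amplitudes (~0.083 Δf/f) exceed echo amplitudes, which in
turn exceed the baseline-window measure (~0.014 Δf/f, what window maxima
yield in silence) — the signed-rank test on the echo-vs-baseline contrast is
decisive even in one session.  Echo responses lag their anticipated times by
~0.24 s, roughly three times the sound-evoked latency.

The same workflow is available from the shell:

```bash
echotune simulate --config run.yaml --seed 1   # traces.csv, protocol.json, ground_truth.csv, events.csv
echotune analyze  --config run.yaml            # transients, summaries, tuning, delta, population, spatial
echotune report   <out_dir>                    # human-readable report.md
```

`analyze` accepts any trace table with a `time_s` column plus one
`neuron_<id>` column per ROI, together with a `protocol.json` describing the
tone trains, so real recordings can be dropped in place of the simulator's
output.  All thresholds, window sizes, the classification α and the
calibration preset (`anesthetized` | `awake`) live in a validated YAML
config; unknown keys are rejected.

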