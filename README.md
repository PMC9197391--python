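# pairclamp

Analysis toolkit for paired patch-clamp recordings, together with a
synthetic-trace generator that provides exact ground truth for every
estimator. It covers the complete quantitative workflow of a paired
recording study:

- **recordings** — domain types (`Trace`, `Sweep`, `Recording`,
  `PairRecording`), a diffable plain-text on-disk format (one CSV per sweep
  plus a JSON sidecar), recording QC (leak > 25 pA or seal < 1 GΩ fails),
  and half-open window extraction.
- **synth** — exponential integrate-and-fire membrane with a spliced
  stereotyped spike waveform (take-off exactly at the true threshold),
  depressing synapses with per-trial failures (release-fraction/recovery
  recursion), Poisson EPSP barrages with shared-input pair coupling, and
  reproducible cohorts (default: 28 pairs, 7 connected) with a truth
  manifest.
- **intrinsic** — spike detection (smoothed dV/dt criterion, default
  1.5 mV/ms, with a 20 mV excursion gate), phase-plot firing threshold,
  F-I curves (counts, mean instantaneous and first-two-spike frequency),
  rheobase, I-V-slope input resistance, median resting potential.
- **synaptic** — pulse-aligned evoked EPSC/EPSP amplitudes with
  failures averaged in, monosynaptic classification (amplitude > 1.5 noise
  SD and latency 2 ± 1 ms), paired-pulse ratio, and spontaneous-EPSP
  detection (low-pass baseline subtraction, 0.3–10 mV window).
- **correlation** — pairwise correlation of spontaneous activity
  (baseline-subtracted voltage, or binned spike counts) over the first
  minutes of simultaneous recording, plus group contrasts.
- **stats** — exact two-sided Wilcoxon signed-rank and Mann-Whitney tests
  (full permutation null for small n, tie-exact; normal approximation
  beyond), median ± SEM group summaries.
- **pipeline / cli** — end-to-end orchestration producing deterministic CSV
  tables (`pairs`, `connections`, `correlations`, `epsp`, `intrinsic`,
  `group_stats`) and a run manifest.

Units throughout: mV, pA, ms, MΩ, pF; traces sampled at 10 kHz by default.

## CLI

```bash
# Generate a synthetic cohort with a truth manifest
pairclamp simulate --out cohort/ --seed 1 --n-pairs 28 --n-connected 7

# Per-stage analyses
pairclamp qc cohort/pair_000/presyn_train_before/post
pairclamp synaptic cohort/pair_000/presyn_train_before
pairclamp correlate cohort/pair_000/spontaneous_before --method filtered_voltage
pairclamp intrinsic some_iv_recording_dir/

# Full pipeline (simulate + analyze, deterministic under --seed)
pairclamp run --out report/ --seed 1 --protocols presyn_train,spontaneous,iv_steps
```

## Library example

```python
from pairclamp.synth import CohortSpec, iter_cohort
from pairclamp.intrinsic import detect_spikes
from pairclamp.synaptic import evoked_response, classify_connection

spec = CohortSpec(protocols=("presyn_train",), conditions=("before",))
for pair in iter_cohort(spec, seed=1):
    rec = pair.recordings[("presyn_train", "before")]
    trains = [detect_spikes(sw.voltage, sweep_index=i)
              for i, sw in enumerate(rec.pre.sweeps)]
    call = classify_connection(evoked_response(rec, trains))
    assert call.connected == pair.connected
```
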