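# cortexwave

Simulation and analysis of two mesoscale cortical functional states in
mouse sensory cortex:

* **SWA (slow-wave activity)** — bimodal activity in which stereotyped,
  cortex-wide calcium/LFP waves (~0.1 Hz) propagate at ~30 mm/s, mostly
  in the anterior→posterior direction, separated by silent periods.
  Sensory stimuli reliably trigger such waves (~90% of the time) *unless*
  they arrive within a ~2-s refractory period after the previous wave.
* **PA (persistent activity)** — continuous, small-amplitude fluctuations
  with LFP power around 15 Hz and short-latency, spatially confined
  (~7 mm²) evoked responses.

The package is aimed at people analysing fibre-photometry traces,
wide-field calcium movies, and LFP recordings of these states.  Because
the reference recordings for this kind of analysis are typically not
publicly deposited, `cortexwave` ships a first-class synthetic-data
generator with exact ground truth, so that every estimator can be
validated by parameter recovery.

## What it computes

| module       | contents |
|--------------|----------|
| `synthgen`   | ground-truth generator: renewal wave process with hard refractory period τᵣ, plane-wave propagation (speed ~ N(30.5, 5.3²) mm/s), stimulus gating (p = 0.90 outside τᵣ), photometry / wide-field / LFP renderers |
| `photometry` | df/f normalization (`raw / mean(baseline) − 1`), 20-Hz Gaussian low-pass, threshold event detection with onset refinement, stimulus-locked latencies, shuffled-onset controls, cross-correlograms, inter-regional delays |
| `widefield`  | %df/f with pre-stimulus reference frame, stimulus-triggered averages, 3.5-SD pixel onset-latency maps, response areas, velocity fields `v = 1/|∇t|` from the latency-map gradient, activation-probability histograms with animal-level permutation tests |
| `spectral`   | multitaper (Slepian-taper) spectrograms, band-limited log₁₀ fold change of stimulus responses (sub-gamma 0.5–35 Hz, gamma 35–200 Hz, total 0.5–200 Hz), 4-SD power-threshold slow-wave onset detection, refractory labelling |
| `refractory` | τᵣ estimation: stimulus success rate binned by time since the last spontaneous wave (0.5-s bins); τᵣ = lower edge of the first bin with success rate strictly > 90% |
| `circstats`  | speed-weighted polar distributions of propagation directions and a two-sample Kuiper test `V = max(F_A−F_B) + max(F_B−F_A)` with permutation significance |

A thin `cortexwave` CLI wraps the common pipelines
(`simulate`, `detect`, `latency`, `xcorr`, `velocity`, `sgram`,
`foldchange`, `swonsets`, `refractory`, `kuiper`).

## Worked example

```python
import numpy as np
from cortexwave import (SimConfig, FieldGeometry, generate_spontaneous_events,
                        generate_stimulus_train, apply_stimulus_gating,
                        render_photometry, detect_events, response_latency,
                        interregion_delays, time_since_last,
                        estimate_refractory_period, label_refractory)
from cortexwave.recovery import preprocess_trace

cfg = SimConfig(duration_s=600.0, seed=42)        # 10 min of SWA
geom = FieldGeometry()
gt = generate_spontaneous_events(cfg, geom)
stim = generate_stimulus_train("somatosensory", n_stimuli=50, isi_s=10.0,
                               start_s=5.0)
gt = apply_stimulus_gating(stim, gt, cfg)

traces = render_photometry(gt, geom, cfg)         # raw fluorescence, S1 + V1
events = {site: detect_events(preprocess_trace(tr))
          for site, tr in traces.items()}

delays, frac = interregion_delays(events["S1"], events["V1"])
dff = preprocess_trace(traces["S1"])
lat, _ = response_latency(dff, stim, mode="swa_onset", window_s=2.0,
                          events=events["S1"])
outside = ~label_refractory(stim, events["S1"].onset_s, window_s=2.0)
ok = outside & np.isfinite(lat) & (lat <= 0.5)

spont = gt.site_onsets("S1", spontaneous_only=True)
intervals = time_since_last(stim, spont)
onsets = gt.site_onsets("S1")
success = np.array([np.any((onsets > s) & (onsets <= s + 0.5))
                    for s in stim.onsets_s])
est = estimate_refractory_period(intervals, success)
```

prints (via the surrounding report statements):

```
detected 112 events in S1, 112 in V1 (ground truth: 114)
S1 leads V1 in 74% of 112 matched waves (mean S1->V1 delay 46 ms)
evoked S1 latency outside refractory: 89 ms over 32 responses
refractory period estimate: 2.5 s
```

Reading the numbers: the detector recovers 112 of the 114 true waves at
both fibres.  S1 leads in 74% here because this recording mixes
spontaneous waves (anterior origin in 60% of cases) with forepaw-evoked
waves, which always start in S1.  The evoked onset latency is the
forepaw→S1 value (~98 ms nominal; 89 ms is within the sampling spread of
32 responses with per-trial jitter plus occasional coincident spontaneous
waves).  The refractory estimate from only 50 stimuli lands one bin above
the true 2.0 s — the binned >90% criterion needs several hundred stimuli
to stabilise (see `docs/methods.md`).

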