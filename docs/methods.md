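# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `cortexwave`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Positions are stereotaxic millimetres (AP negative = posterior, ML
positive = lateral).  The imaged field is a rectangle with its anterior
edge at AP = 0 and medial edge at ML = 0; image rows run
anterior→posterior, columns medial→lateral.  Direction angles use 0 =
anterior, +π/2 = lateral, so a wave travelling posteriorly has direction
π and an anterolaterally propagating visual response sits near +π/6.
The default field is 4.8 × 4.8 mm (48 × 48 pixels at 0.1 mm pitch),
chosen so the field of view is ≈23 mm² — the scale at which evoked
slow waves engage essentially the whole imaged window.  Recording sites
default to S1 (−0.2, 2.5) and V1 (−3.8, 2.0), 3.63 mm apart.

## Generative model (synthgen)

**Spontaneous slow waves.**  A renewal process with inter-event interval
τᵣ + Exp(μ − τᵣ), where μ = 60/`wave_rate_per_min`; the hard refractory
period is honoured by construction and the mean rate equals the nominal
rate (default 10/min, i.e. waves "around 0.1 Hz").  Each wave is a plane
wavefront with

* origin: anterior (S1-level AP band) with probability 0.6, else
  posterior (V1-level band), ML jittered (SD 0.3 mm);
* direction: posterior (π) for anterior origins, anterior (0) for
  posterior origins, with angular jitter SD 0.26 rad (≈15°);
* speed: Normal(30.5, 5.3) mm/s truncated at 1 mm/s.

Activation of a point p at time t₀ + (p − origin)·u / v.  Because site
onsets follow deterministically from the plane-wave geometry, the
S1-leading fraction equals the anterior-origin probability (up to
direction jitter), and the S1→V1 delay is ≈3.6 mm / 30 mm/s ≈ 120 ms.
After drawing events, a greedy thinning pass enforces the per-site
refractory spacing that direction jitter could otherwise compress.

**Stimulus gating.**  For each stimulus, the time since the last wave
onset at the stimulus' primary sensory site decides the gate: outside τᵣ
a wave is evoked with probability 0.90 at a modality/site-specific
latency (means 98/115 ms at the contralateral primary site; per-trial
jitter SD equal to the reported standard errors, 4–11 ms); inside τᵣ the
success probability drops to `p_refractory` (default 0.2, a free
parameter — only the outside behaviour is constrained by the reference
conditions) and the latency jitter is inflated threefold (response-time
variability is larger inside the refractory window).  Evoked waves
originate exactly at the primary site and are otherwise identical to
spontaneous waves.  A spontaneous wave already rising between the
stimulus and the evoked onset absorbs the evoked wave ("merged", with
the spontaneous onset); spontaneous waves due within τᵣ *after* an
evoked wave are suppressed.  History is never rewritten: waves that
already occurred are never removed.

**Rendering.**  Calcium kernel k(t) = (1 − e^(−t/τ_rise)) e^(−t/τ_decay),
peak-normalized, τ_rise = 50 ms, τ_decay = 1 s (typical OGB-1/GCaMP6
scale).  Photometry = baseline × (1 + Σ kernels + noise); wide-field
movies place the kernel at each pixel's activation time.  Spontaneous
SWA waves span the whole field; every *evoked* response is restricted to
the N pixels nearest its initiation site with N = area/pitch² (the
configured response areas: 22.8/23.1 mm² in SWA ≈ the whole field,
6.9/7.5 mm² in PA), which makes the rendered response area exact to one
pixel.  PA background activity is a sum of a global mode and six smooth
spatial Gaussian modes with band-limited slow time courses, so the
field-of-view mean fluctuates continuously without ever being fully
active or silent.  LFP: SWA = a low noise floor plus burst-gated
broadband (0.5–100 Hz) noise under a fast double-exponential envelope
(rise 20 ms, decay 300 ms) at each wave onset; PA = narrowband noise at
15 ± 2 Hz over low-passed background; both states add an 80-ms
Hann-windowed gamma-band (35–200 Hz) packet 5 ms after each stimulus at
the stimulated modality's primary site only — the state-independent
primary sensory response.  Noise is i.i.d. Gaussian per sample/pixel
with SD `noise_sd` (default 0.05) times the event amplitude.  All
randomness derives from `SimConfig.seed` through per-operation
`numpy.random.Generator` streams; identical configurations are
bit-identical.

**What the generator does not emulate.**  No biophysics, hemodynamics,
wavefront curvature, amplitude attenuation with distance, motion or
photobleaching artefacts, or behavioural state transitions.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated statistical structure, not robustness to every artefact of real
recordings.

## Photometry analysis

* **df/f**: raw / mean(baseline window) − 1; the baseline window is a
  quiet second (≥0.5 s), located automatically by
  `find_quiet_baseline` as the window with the lowest rolling mean.
* **Low-pass**: Gaussian kernel with −3 dB at the cutoff
  (σ = √(ln 2)/(2π f_c); 20 Hz default), zero-phase.
* **Event detection**: baseline statistics come from the amplitude
  histogram mode, with the noise SD estimated one-sidedly from samples
  *below* the mode (waves only deflect upward), which stays correct at
  any event occupancy — iterative threshold masking fails above ~50%
  occupancy.  Events are supra-threshold runs (mean + 3 SD) of at least
  0.2 s, merged across gaps < 1 s; runs containing several peaks of
  prominence ≥ 10 baseline SDs are split at the intervening valleys
  (waves a few seconds apart ride on the previous decay tail and never
  return to baseline).  Onsets are refined by back-extrapolating the
  steepest 5-ms rise tangent to the local pre-peak floor; this is
  insensitive to baseline contamination and biases onsets by only a few
  ms (≈ −3 ms at default noise).  The detector's contract is a df/f,
  low-pass-filtered trace.
* **Latencies**: `swa_onset` = time to the next detected onset within
  the window; `pa_peak` = time to the amplitude maximum within a 2-s
  window.  Missing responses are NaN, never zero, so means pool over
  successes only.
* **Shuffle control**: onsets jittered uniformly within a 2-s range
  centred on the true onset, independently per stimulus (the shuffle
  distribution itself is a design choice; only the range is fixed).
* **Delays**: events matched greedily by nearest onset (smallest |Δ|
  first, 1-s window); delay = onset_b − onset_a, positive = a leads.

## Wide-field analysis

%df/f uses the frame immediately preceding the stimulus as F₀.
Triggered averages normalize each segment to its own F₀ before
averaging.  The onset-latency map thresholds each pixel at pre-stimulus
mean + 3.5 SD (1-s pre-stimulus window by default) and — by default —
linearly interpolates the crossing between the last sub-threshold and
first supra-threshold frame.  Frame-quantized onsets (interpolate=False)
are available but make the gradient degenerate: at 20–40 Hz a wave
crosses the field in only 3–7 frames.

The velocity field median-filters the latency map (3×3), optionally mean
filters it (`smooth_mean_px`), then takes central differences in AP/ML
axes: slowness g = ∇t, speed = 1/|g|, direction = atan2(g_ML, g_AP)
(early→late).  Pixels implying > 1000 mm/s are invalid (near-simultaneous
activation carries no direction), as is a border margin the width of the
filters.  Linear interpolation of a convex rise leaves a sawtooth ripple
in the latency map with spatial period v/(frame_rate × pitch) pixels
(≈7.6 px at 40 Hz, 0.1 mm, 30 mm/s); a mean filter at that scale removes
the ripple without biasing a linear ramp, which is why speed-recovery
pipelines pass `smooth_mean_px=7`.  Even so, per-pixel speeds are
right-skewed (flat patches → near-zero slowness), so speed summaries use
medians — per animal, then across animals — rather than means; the
residual recovery bias is ≈ +5% at 40 Hz with ~40 trials.  Response
area = max simultaneous supra-threshold pixel count over frames in the
1–2-s window × pitch² ("cumulative ever-active" is available as an
option).  Activation histograms min–max normalize the field-of-view mean
trace using robust 1st/99th percentile bounds, making them invariant to
affine intensity rescaling.  Histogram comparison permutes animal group
labels (animals, not pixels or frames, are the exchangeable unit),
counts ties as exceedances (p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1)),
and Bonferroni-adjusts across bins.

## Spectral analysis

Multitaper spectrograms average one-sided Slepian-tapered periodograms
(default: 400-ms window, 200-ms step, time–bandwidth product 4, nine
tapers, fpass 0–40 Hz — the conventional display parameters).  Note that
K = 9 exceeds the well-concentrated taper count 2·TW − 1 = 7 (a warning
is emitted) and the resulting ±10 Hz smoothing bandwidth visibly smears
narrowband peaks: resolving the PA 15-Hz peak needs e.g. a 1-s window
with TW = 2, K = 3.  Power is PSD-scaled so its integral tracks the
signal variance (verified against white noise).

Band-power fold change averages the stimulus-locked segments first, then
band-limits the average (4th-order Butterworth, zero-phase) and reports
log₁₀ of mean post-window power (0–1.5 s) over mean pre-window power
(−0.3 to −0.1 s).  Segments are padded by ≥ 2/f_low before filtering so
the 0.5-Hz high-pass transient stays outside the analysis windows.  Both
windows use band-limited variance (no separate multitaper machinery);
the estimate is scale-invariant, and on unlocked signals it scatters
around 0 with a spread set by the ~14 degrees of freedom of the 200-ms
pre-window — single-recording values of ±0.5 log units are expected
noise.  Power-threshold slow-wave detection squares the signal, smooths
over 100 ms, and takes upward crossings of mean + 4 SD, merging
crossings within 0.5 s; thresholds are relative, so detection is
amplitude-scale invariant.

## Refractory estimation

Stimuli are binned by time since the last spontaneous wave (0.5-s bins
from 0); the refractory period is the lower edge of the first bin whose
success rate is *strictly* greater than 0.90 (">90%"), with empty bins
skipped, never passed.  A success is a wave onset within the success
window after the stimulus — default 0.5 s, parameterized because the
stated figure-of-merit window is ambiguous at face value.  Estimation is
knife-edge by design: the true outside-refractory success probability is
exactly 0.90, so a bin passes only through the small excess contributed
by coincident spontaneous waves (asymptotically ≈0.91 at the default
wave rate).  With the standard 500 pooled stimuli (~40–50 per bin), a
single run lands exactly at 2.0 s roughly three times out of four and
otherwise one bin high; the modal estimate over a handful of runs is
stable, estimates never fall below τᵣ − one bin, and several thousand
stimuli would be needed to make single runs deterministic.  This
finite-sample property is inherent to the binned >90% criterion, not to
the implementation.

## Circular statistics

The weighted polar distribution pools valid velocity vectors across
animals, each direction weighted by its speed, over 36 bins on (−π, π].
The two-sample Kuiper statistic V = max(F_A − F_B) + max(F_B − F_A) is
computed on weighted empirical CDFs evaluated at the pooled sample
points (plus the flat stretch before the first point); V is exactly
rotation invariant and reduces to the classical statistic for equal
weights (verified against an O(n²) brute-force oracle).  Because
tabulated Kuiper null distributions do not apply to speed-weighted
samples, significance uses label permutation — exact under the null for
any weighting.  With small *unweighted* samples the statistic is heavily
tied and permutation p-values become conservative; the uniformity
guarantee applies to continuous (weighted) data.  Pixel vectors within
an animal are dependent, so an animal-level permutation unit is
available via per-vector unit labels (default is per-vector).

## Problem sizes used in validation

Recovery experiments use: 500 gated stimuli pooled over 4 simulated
animals and both modalities (refractory period); 4 animals × 30 stimuli
(evoked probability); 120 spontaneous waves with dual-site detection
(S1-leading fraction); 80–130 stimuli per modality (latencies);
3 animals × 40 stimuli at 40 Hz (propagation speed); 20 stimuli at 40 Hz
(response area).  These sizes put Monte-Carlo error comfortably inside
each quantity's tolerance while keeping a full validation run in the
order of a minute.

## Known limitations

* The latency-map interpolation and the 7-px mean smoothing are tuned to
  the frame-rate/speed regime of the default conditions; very different
  regimes need a different `smooth_mean_px` (≈ v/(rate·pitch)).
* The fold-change estimator is noisy on unlocked signals (short
  pre-window, by definition of the procedure).
* Event-wise statistics on mixed recordings (spontaneous + evoked)
  include coincident spontaneous waves; latency means are contaminated
  at the percent level.
* `p_refractory`, the PA rendering amplitudes, and the LFP band gains
  are plausible but unconstrained by the reference conditions; analyses
  that depend on them quantitatively should treat them as free knobs.
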