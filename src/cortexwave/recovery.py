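"""End-to-end parameter-recovery experiments on synthetic data.

Each function simulates a complete experiment at the generator's default
conditions, runs the corresponding analysis pipeline on the rendered data,
and returns the recovered quantity — the package's self-validation: the
analysis should recover the refractory period (2.0 s), the evoked success
probability (~90%), the fraction of waves reaching S1 first (~60%), the
modality-specific evoked latencies (98 / 115 ms), the propagation speed
(~30.5 mm/s) and the evoked response area (~22.8 mm^2) that the generator
was built with.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .config import PRIMARY_SITE, SimConfig
from .geometry import FieldGeometry
from .photometry import (
    detect_events,
    find_quiet_baseline,
    interregion_delays,
    lowpass_gaussian,
    normalize_dff,
    response_latency,
)
from .refractory import estimate_refractory_period, time_since_last
from .spectral import label_refractory
from .synthgen import (
    apply_stimulus_gating,
    generate_spontaneous_events,
    generate_stimulus_train,
    render_photometry,
    render_widefield,
)
from .widefield import (
    mean_velocity_vector,
    onset_latency_map,
    response_area,
    stimulus_triggered_average,
    velocity_field,
)

__all__ = [
    "preprocess_trace",
    "recover_refractory_period",
    "recover_evoked_probability",
    "recover_leader_fraction",
    "recover_evoked_latency",
    "recover_propagation_speed",
    "recover_response_area",
]


def preprocess_trace(trace):
    """df/f on the automatically located quietest second, 20-Hz low-pass."""
    return lowpass_gaussian(normalize_dff(trace, find_quiet_baseline(trace)))


def _gated_swa(seed: int, modality: str, n_stimuli: int, isi_s: float,
               frame_rate_hz: float = 20.0, start_s: float = 10.0):
    cfg = SimConfig(duration_s=n_stimuli * isi_s + start_s + 10.0,
                    seed=seed, frame_rate_hz=frame_rate_hz)
    gt = generate_spontaneous_events(cfg, FieldGeometry())
    stim = generate_stimulus_train(modality, n_stimuli=n_stimuli,
                                   isi_s=isi_s, start_s=start_s)
    return apply_stimulus_gating(stim, gt, cfg), stim, cfg


def recover_refractory_period(seed: int, n_stimuli: int = 500,
                              n_animals: int = 4,
                              isi_s: float = 10.0,
                              success_window_s: float = 0.5,
                              bin_s: float = 0.5,
                              criterion: float = 0.90):
    """Refractory period from 500 gated stimuli.

    Stimuli are pooled across simulated animals and both modalities (the
    standard pooling for this estimate); each stimulus is binned by time
    since the last spontaneous wave at its primary sensory site, counting
    a success when a wave onset follows within the success window, and
    the estimate is the lower edge of the first 0.5-s bin whose success
    rate strictly exceeds the criterion.
    """
    rng = np.random.default_rng([seed, 0])
    per = max(n_stimuli // n_animals, 1)
    modalities = ("somatosensory", "visual")
    intervals_all, success_all = [], []
    for a in range(n_animals):
        sub = int(rng.integers(0, 2**31 - 1))
        mod = modalities[a % 2]
        site = PRIMARY_SITE[mod]
        gt, stim, _ = _gated_swa(sub, mod, per, isi_s)
        spont = gt.site_onsets(site, spontaneous_only=True)
        onsets = gt.site_onsets(site)
        intervals_all.append(time_since_last(stim, spont))
        success_all.append(np.array([
            np.any((onsets > s) & (onsets <= s + success_window_s))
            for s in stim.onsets_s]))
    return estimate_refractory_period(np.concatenate(intervals_all),
                                      np.concatenate(success_all),
                                      bin_s=bin_s, criterion=criterion)


def recover_evoked_probability(seed: int, n_animals: int = 4,
                               n_stimuli: int = 30, isi_s: float = 10.0,
                               success_window_s: float = 0.5) -> Dict:
    """Evoked success probability outside the refractory window.

    Per simulated animal, runs the full detection pipeline (df/f, 20-Hz
    Gaussian low-pass, event detection) on the S1 photometry trace during
    forepaw-type stimulation, labels refractory stimuli from the detected
    event train, and counts a success when a detected onset falls within
    the success window.  Returns the across-animal mean percentage.
    """
    rng = np.random.default_rng([seed, 1])
    per_animal = []
    n_outside_total = 0
    for _ in range(n_animals):
        sub = int(rng.integers(0, 2**31 - 1))
        gt, stim, cfg = _gated_swa(sub, "somatosensory", n_stimuli, isi_s,
                                   start_s=5.0)
        trace = render_photometry(gt, gt.geometry, cfg, sites=["S1"])["S1"]
        events = detect_events(preprocess_trace(trace))
        refractory = label_refractory(stim, events.onset_s,
                                      window_s=cfg.refractory_s)
        success = np.array([
            np.any((events.onset_s > s)
                   & (events.onset_s <= s + success_window_s))
            for s in stim.onsets_s])
        outside = ~refractory
        if outside.sum():
            per_animal.append(100.0 * success[outside].mean())
            n_outside_total += int(outside.sum())
    return {"mean_percent": float(np.mean(per_animal)),
            "per_animal_percent": per_animal,
            "n_stimuli_outside": n_outside_total}


def recover_leader_fraction(seed: int, n_events: int = 120,
                            match_window_s: float = 1.0) -> Dict:
    """Percentage of spontaneous waves whose detected S1 onset precedes V1.

    Renders dual-site photometry for exactly ``n_events`` spontaneous
    waves, detects events independently at both fibres, matches them by
    nearest onset, and reports the S1-leading percentage.
    """
    geom = FieldGeometry()
    cfg = SimConfig(duration_s=n_events * 8.0 + 60.0, seed=seed)
    gt = generate_spontaneous_events(cfg, geom)
    if gt.n_events < n_events:
        raise RuntimeError("simulation too short for requested event count")
    keep = np.zeros(gt.n_events, dtype=bool)
    keep[:n_events] = True
    from .synthgen import _select_events

    _select_events(gt, keep)
    cfg.duration_s = float(gt.event_time_s.max() + 10.0)
    traces = render_photometry(gt, geom, cfg)
    ev = {site: detect_events(preprocess_trace(traces[site]))
          for site in ("S1", "V1")}
    delays, frac = interregion_delays(ev["S1"], ev["V1"],
                                      match_window_s=match_window_s)
    return {"percent_s1_leading": 100.0 * frac,
            "n_matched": int(len(delays)),
            "mean_delay_ms": float(np.mean(delays) * 1000.0)}


def recover_evoked_latency(seed: int, modality: str,
                           n_stimuli: int = 130, isi_s: float = 10.0,
                           window_s: float = 2.0,
                           success_window_s: float = 0.5) -> Dict:
    """Mean stimulus-to-wave-onset latency (ms) at the primary site.

    Runs the detection pipeline on the primary-site photometry trace and
    takes, for each stimulus outside the refractory window, the time to
    the next detected onset; responses within the success window count as
    evoked and enter the mean.
    """
    site = PRIMARY_SITE[modality]
    gt, stim, cfg = _gated_swa(seed, modality, n_stimuli, isi_s, start_s=5.0)
    trace = render_photometry(gt, gt.geometry, cfg, sites=[site])[site]
    dff = preprocess_trace(trace)
    events = detect_events(dff)
    lat, skipped = response_latency(dff, stim, mode="swa_onset",
                                    window_s=window_s, events=events)
    refractory = label_refractory(stim, events.onset_s,
                                  window_s=cfg.refractory_s)
    ok = (~refractory) & (~skipped) & np.isfinite(lat) \
        & (lat <= success_window_s)
    return {"mean_latency_ms": float(np.mean(lat[ok]) * 1000.0),
            "n_responses": int(ok.sum())}


def recover_propagation_speed(seed: int, n_animals: int = 3,
                              n_stimuli: int = 40,
                              modality: str = "visual",
                              frame_rate_hz: float = 40.0,
                              smooth_mean_px: int = 7) -> Dict:
    """Median propagation speed (mm/s) from wide-field latency gradients.

    Per animal: a stimulus-triggered average movie of ~40 evoked waves
    (typical trial counts per modality), the 3.5-SD onset-latency map, and
    the gradient velocity field.  The summary is the median over animals
    of each animal's median pixel speed — robust both to near-simultaneous
    pixels within an animal and to an occasional animal whose average is
    distorted by coincident spontaneous waves.
    """
    rng = np.random.default_rng([seed, 2])
    per_animal = []
    directions = []
    for _ in range(n_animals):
        sub = int(rng.integers(0, 2**31 - 1))
        gt, stim, cfg = _gated_swa(sub, modality, n_stimuli, isi_s=10.0,
                                   frame_rate_hz=frame_rate_hz, start_s=5.0)
        movie = render_widefield(gt, gt.geometry, cfg)
        sta = stimulus_triggered_average(movie, stim, window_s=(-1.0, 3.0))
        field = velocity_field(onset_latency_map(sta),
                               smooth_mean_px=smooth_mean_px)
        _, spd = field.vectors()
        per_animal.append(float(np.median(spd)))
        _, direction = mean_velocity_vector(field)
        directions.append(direction)
    return {"median_speed_mm_s": float(np.median(per_animal)),
            "per_animal_mm_s": per_animal,
            "mean_direction_deg": float(np.degrees(np.mean(directions)))}


def recover_response_area(seed: int, modality: str = "visual",
                          n_stimuli: int = 20,
                          frame_rate_hz: float = 40.0,
                          window_s=(1.0, 2.0)) -> Dict:
    """Evoked response area (mm^2) from the 3.5-SD pipeline on an SWA
    triggered-average movie."""
    gt, stim, cfg = _gated_swa(seed, modality, n_stimuli, isi_s=10.0,
                               frame_rate_hz=frame_rate_hz, start_s=5.0)
    movie = render_widefield(gt, gt.geometry, cfg)
    sta = stimulus_triggered_average(movie, stim, window_s=(-1.0, 3.0))
    area = response_area(sta, window_s=window_s)
    return {"area_mm2": float(area), "n_stimuli": sta.n_stimuli}
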