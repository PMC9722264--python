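"""Synthetic generator for two cortical functional states.

Produces fibre-photometry traces, LFP-like signals, and wide-field movies
with exact ground truth (event times, origins, speeds, directions, evoked
success flags and latencies), so that every analysis stage of the package
can be validated by parameter recovery.

Model
-----
* SWA (slow-wave activity): a renewal process of cortex-wide waves.  The
  inter-event interval is a hard refractory period ``tau_r`` plus an
  exponential tail chosen so the mean rate matches ``wave_rate_per_min``.
  Each wave is a plane wavefront with a constant speed drawn from a
  truncated normal and a direction tied to its origin: anterior origins
  (S1-level band, probability ``anterior_origin_prob``) travel posteriorly,
  posterior origins travel anteriorly.  The activation time of a point
  ``p`` is ``t0 + (p - origin) . u / speed`` with ``u`` the direction unit
  vector.
* Stimulus gating: a stimulus arriving at least ``tau_r`` after the last
  wave at its primary sensory site evokes a new wave with probability
  ``p_evoke`` at a site- and modality-specific latency; inside the
  refractory window the success probability drops to ``p_refractory`` and
  the latency jitter is inflated.  Evoked waves originate at the primary
  site and are otherwise identical to spontaneous ones.
* PA (persistent activity): continuous band-limited fluctuations around
  ``pa_band_hz`` with short-latency, spatially confined evoked transients.

All randomness derives from ``SimConfig.seed`` through independent
``numpy.random.Generator`` streams per operation, so identical configs give
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .config import PRIMARY_SITE, SimConfig
from .geometry import FieldGeometry, unit_vector, wrap_angle

__all__ = [
    "StimulusTrain",
    "GroundTruth",
    "generate_stimulus_train",
    "generate_spontaneous_events",
    "apply_stimulus_gating",
    "render_photometry",
    "render_widefield",
    "render_lfp",
    "calcium_kernel",
]


# ----------------------------------------------------------------------
# kernels and noise helpers
# ----------------------------------------------------------------------

def calcium_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Peak-normalized double-exponential kernel, zero for t < 0.

    ``k(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay)``, scaled to peak 1.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise_s))
                 * np.exp(-np.maximum(t, 0) / tau_decay_s), 0.0)
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1.0 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    return k / peak


def kernel_peak_delay(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time from kernel onset to its peak (s)."""
    return tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: Tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase band-limited Gaussian noise, normalized to unit SD."""
    x = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = max(band[0], 1e-3) / nyq
    hi = min(band[1], 0.99 * nyq) / nyq
    if hi <= lo:
        raise ValueError(f"band {band} incompatible with fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int = 1, floor: float = 1.0) -> np.ndarray:
    """Normal draws truncated below at ``floor`` (re-draw, then clip)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(10):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, floor)


# ----------------------------------------------------------------------
# stimulus trains
# ----------------------------------------------------------------------

@dataclass
class StimulusTrain:
    """Timed sensory stimuli of one modality.

    ``onsets_s`` are strictly increasing stimulus (or pulse) onset times.
    ``pulse_ms`` and ``amplitude_ma`` are acquisition metadata.
    """

    onsets_s: np.ndarray
    modality: str
    pulse_ms: float = 10.0
    amplitude_ma: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.pulse_ms <= 0:
            raise ValueError("pulse_ms must be positive")
        if self.onsets_s.ndim != 1:
            raise ValueError("onsets_s must be 1-D")
        if len(self.onsets_s) > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_s)


def generate_stimulus_train(
    modality: str,
    n_stimuli: int = 1,
    isi_s: float | Tuple[float, float] = 10.0,
    train_spec: Optional[Tuple[float, float]] = None,
    start_s: float = 0.0,
    pulse_ms: float = 10.0,
    seed: Optional[int] = None,
) -> StimulusTrain:
    """Build a stimulus train of single pulses or pulse-train blocks.

    Parameters
    ----------
    modality : {"visual", "somatosensory"}
    n_stimuli : int
        Number of single pulses, or number of blocks if ``train_spec``.
    isi_s : float or (lo, hi)
        Inter-stimulus (inter-block) interval; a tuple draws each interval
        uniformly from [lo, hi] (jittered paradigm).
    train_spec : (rate_hz, duration_s), optional
        Block paradigm: each block contains pulses at ``rate_hz`` for
        ``duration_s`` (e.g. ``(3, 4)`` -> 12 pulses per block).
    """
    if modality not in PRIMARY_SITE:
        raise ValueError(f"unknown modality {modality!r}")
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = np.random.default_rng(seed)
    if np.isscalar(isi_s):
        if isi_s <= 0:
            raise ValueError("isi_s must be positive")
        gaps = np.full(n_stimuli - 1, float(isi_s))
    else:
        lo, hi = isi_s
        if lo <= 0 or hi < lo:
            raise ValueError("isi range must satisfy 0 < lo <= hi")
        gaps = rng.uniform(lo, hi, size=n_stimuli - 1)
    starts = start_s + np.concatenate([[0.0], np.cumsum(gaps)])
    desc = f"single pulses, ISI {isi_s} s"
    if train_spec is not None:
        rate_hz, dur_s = train_spec
        if rate_hz <= 0 or dur_s <= 0:
            raise ValueError("train rate and duration must be positive")
        n_pulses = int(round(rate_hz * dur_s))
        offsets = np.arange(n_pulses) / rate_hz
        starts = (starts[:, None] + offsets[None, :]).ravel()
        desc = f"{rate_hz} Hz x {dur_s} s trains, ISI {isi_s} s"
    return StimulusTrain(onsets_s=starts, modality=modality,
                         pulse_ms=pulse_ms, description=desc)


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True events and stimulus outcomes of one simulated recording.

    Event arrays are aligned (one entry per wave).  ``event_time_s`` is the
    wave onset at its origin; per-site onsets follow from the plane-wave
    geometry via :meth:`site_onsets`.  Stimulus arrays are populated by
    :func:`apply_stimulus_gating`.
    """

    config: SimConfig
    geometry: FieldGeometry
    event_time_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    origin_ap_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    origin_ml_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    speed_mm_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    direction_rad: np.ndarray = field(default_factory=lambda: np.empty(0))
    evoked: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    merged: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    stim_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    event_modality: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    # stimulus bookkeeping
    stim_onset_s: Optional[np.ndarray] = None
    stim_modality: Optional[np.ndarray] = None
    stim_success: Optional[np.ndarray] = None
    stim_refractory: Optional[np.ndarray] = None
    stim_latency_ms: Optional[np.ndarray] = None
    warning: Optional[str] = None

    @property
    def n_events(self) -> int:
        return len(self.event_time_s)

    def site_onsets(self, site: str, spontaneous_only: bool = False,
                    evoked_only: bool = False) -> np.ndarray:
        """Wave-onset times (s) at a named site, sorted ascending."""
        if self.n_events == 0:
            return np.empty(0)
        p = self.geometry.site_position(site)
        u = unit_vector(self.direction_rad)
        rel = p[None, :] - np.stack([self.origin_ap_mm, self.origin_ml_mm], axis=1)
        onsets = self.event_time_s + (rel * u).sum(axis=1) / self.speed_mm_s
        if spontaneous_only:
            onsets = onsets[~self.evoked]
        elif evoked_only:
            onsets = onsets[self.evoked]
        return np.sort(onsets)

    def stim_merged(self) -> np.ndarray:
        """Per-stimulus flag: True where the evoked wave merged with a
        near-coincident spontaneous one (latency then reflects the merged
        wave's onset, not a fresh evoked latency)."""
        if self.stim_onset_s is None:
            return np.empty(0, dtype=bool)
        out = np.zeros(len(self.stim_onset_s), dtype=bool)
        for idx in range(self.n_events):
            k = int(self.stim_index[idx])
            if k >= 0 and self.merged[idx]:
                out[k] = True
        return out

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "event_time_s": arr(self.event_time_s),
            "origin_ap_mm": arr(self.origin_ap_mm),
            "origin_ml_mm": arr(self.origin_ml_mm),
            "speed_mm_s": arr(self.speed_mm_s),
            "direction_rad": arr(self.direction_rad),
            "evoked": arr(self.evoked),
            "merged": arr(self.merged),
            "stim_index": arr(self.stim_index),
            "event_modality": [m if m is None else str(m) for m in self.event_modality],
            "stim_onset_s": arr(self.stim_onset_s),
            "stim_modality": arr(self.stim_modality),
            "stim_success": arr(self.stim_success),
            "stim_refractory": arr(self.stim_refractory),
            "stim_latency_ms": arr(self.stim_latency_ms),
            "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, d: dict, config: SimConfig, geometry: FieldGeometry) -> "GroundTruth":
        def get(key, dtype=float):
            v = d.get(key)
            return None if v is None else np.asarray(v, dtype=dtype)
        return cls(
            config=config, geometry=geometry,
            event_time_s=get("event_time_s"),
            origin_ap_mm=get("origin_ap_mm"),
            origin_ml_mm=get("origin_ml_mm"),
            speed_mm_s=get("speed_mm_s"),
            direction_rad=get("direction_rad"),
            evoked=get("evoked", bool),
            merged=get("merged", bool),
            stim_index=get("stim_index", int),
            event_modality=np.asarray(d.get("event_modality", []), dtype=object),
            stim_onset_s=get("stim_onset_s"),
            stim_modality=None if d.get("stim_modality") is None
            else np.asarray(d["stim_modality"], dtype=object),
            stim_success=get("stim_success", bool),
            stim_refractory=get("stim_refractory", bool),
            stim_latency_ms=get("stim_latency_ms"),
            warning=d.get("warning"),
        )


# ----------------------------------------------------------------------
# spontaneous wave process
# ----------------------------------------------------------------------

def generate_spontaneous_events(config: SimConfig,
                                geometry: Optional[FieldGeometry] = None) -> GroundTruth:
    """Draw the spontaneous SWA wave train with origins, speeds, directions.

    Inter-event intervals are ``tau_r + Exp(mean_iei - tau_r)`` so the hard
    refractory period is respected by construction and the mean rate equals
    ``wave_rate_per_min``.  After assigning per-event geometry, events are
    greedily thinned so that onsets at *every* recording site are at least
    ``tau_r`` apart (direction jitter can otherwise compress per-site gaps
    slightly below the nominal spacing).
    """
    if config.state != "SWA":
        raise ValueError("spontaneous wave generation requires state='SWA'")
    geometry = geometry or FieldGeometry()
    rng = np.random.default_rng([config.seed, 101])
    tau_r = config.refractory_s
    tail = config.mean_iei_s - tau_r

    times: List[float] = []
    t = rng.uniform(0.0, config.mean_iei_s)
    while t < config.duration_s:
        times.append(t)
        t += tau_r + rng.exponential(tail)
    gt = GroundTruth(config=config, geometry=geometry)
    if not times:
        gt.warning = "duration too short for a single event"
        warnings.warn(gt.warning)
        return gt

    n = len(times)
    anterior = rng.random(n) < config.anterior_origin_prob
    s1 = geometry.site_position("S1")
    v1 = geometry.site_position("V1")
    origin_ap = np.where(anterior, s1[0], v1[0])
    origin_ml = np.where(anterior, s1[1], v1[1]) + rng.normal(
        0.0, config.origin_ml_jitter_mm, size=n)
    origin_ml = np.clip(origin_ml, 0.0, geometry.fov_ml_mm)
    # anterior origins travel posteriorly (pi), posterior origins anteriorly (0)
    direction = np.where(anterior, np.pi, 0.0) + rng.normal(
        0.0, config.direction_jitter_rad, size=n)
    direction = np.asarray(wrap_angle(direction))
    speed = _truncated_normal(rng, config.speed_mean_mm_s, config.speed_sd_mm_s, n)

    gt.event_time_s = np.asarray(times)
    gt.origin_ap_mm = origin_ap
    gt.origin_ml_mm = origin_ml
    gt.speed_mm_s = speed
    gt.direction_rad = direction
    gt.evoked = np.zeros(n, dtype=bool)
    gt.merged = np.zeros(n, dtype=bool)
    gt.stim_index = np.full(n, -1, dtype=int)
    gt.event_modality = np.asarray([None] * n, dtype=object)
    _thin_for_refractory(gt)
    return gt


def _event_site_onset(gt: GroundTruth, i: int, site: str) -> float:
    p = gt.geometry.site_position(site)
    u = unit_vector(gt.direction_rad[i])
    rel = p - np.array([gt.origin_ap_mm[i], gt.origin_ml_mm[i]])
    return float(gt.event_time_s[i] + rel @ u / gt.speed_mm_s[i])


def _thin_for_refractory(gt: GroundTruth, protect: Optional[np.ndarray] = None) -> None:
    """Drop events (never protected ones) so per-site gaps stay >= tau_r."""
    tau_r = gt.config.refractory_s
    sites = list(gt.geometry.sites)
    order = np.argsort(gt.event_time_s, kind="stable")
    keep = np.zeros(gt.n_events, dtype=bool)
    last = {s: -np.inf for s in sites}
    protect = protect if protect is not None else gt.evoked
    for i in order:
        onsets = {s: _event_site_onset(gt, i, s) for s in sites}
        ok = all(onsets[s] - last[s] >= tau_r for s in sites)
        if ok or protect[i]:
            keep[i] = True
            for s in sites:
                last[s] = max(last[s], onsets[s])
    _select_events(gt, keep)


def _select_events(gt: GroundTruth, keep: np.ndarray) -> None:
    for name in ("event_time_s", "origin_ap_mm", "origin_ml_mm", "speed_mm_s",
                 "direction_rad", "evoked", "merged", "stim_index",
                 "event_modality"):
        setattr(gt, name, getattr(gt, name)[keep])


# ----------------------------------------------------------------------
# stimulus gating
# ----------------------------------------------------------------------

def apply_stimulus_gating(
    stimuli: StimulusTrain | Sequence[StimulusTrain],
    ground_truth: GroundTruth,
    config: Optional[SimConfig] = None,
) -> GroundTruth:
    """Augment a spontaneous ground truth with stimulus-evoked waves.

    For each stimulus (processed chronologically, trains of different
    modalities may be mixed) the time since the last wave onset at the
    stimulus' primary sensory site decides the gate: outside the refractory
    window a wave is evoked with probability ``p_evoke``, inside with
    ``p_refractory`` (and inflated latency jitter).  Evoked waves originate
    at the primary site, propagate along the modality's stereotypic
    direction, and may merge with a near-coincident spontaneous wave (the
    stimulus is then linked to that wave and the wave flagged ``merged``).
    Spontaneous waves that would violate the per-site refractory spacing
    after an insertion are removed.
    """
    config = config or ground_truth.config
    geometry = ground_truth.geometry
    rng = np.random.default_rng([config.seed, 102])

    trains = [stimuli] if isinstance(stimuli, StimulusTrain) else list(stimuli)
    onsets = np.concatenate([t.onsets_s for t in trains])
    modalities = np.concatenate([
        np.full(len(t), t.modality, dtype=object) for t in trains])
    order = np.argsort(onsets, kind="stable")
    onsets, modalities = onsets[order], modalities[order]
    if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
        raise ValueError("stimulus onsets must be strictly increasing after merge")

    # mutable event store
    events: List[dict] = []
    for i in range(ground_truth.n_events):
        events.append({
            "t0": float(ground_truth.event_time_s[i]),
            "origin": (float(ground_truth.origin_ap_mm[i]),
                       float(ground_truth.origin_ml_mm[i])),
            "speed": float(ground_truth.speed_mm_s[i]),
            "direction": float(ground_truth.direction_rad[i]),
            "evoked": bool(ground_truth.evoked[i]),
            "merged": False,
            "stim_index": -1,
            "modality": None,
            "dropped": False,
        })

    sites = list(geometry.sites)
    site_pos = {s: geometry.site_position(s) for s in sites}

    def ev_onset(ev: dict, site: str) -> float:
        u = unit_vector(ev["direction"])
        rel = site_pos[site] - np.asarray(ev["origin"])
        return ev["t0"] + float(rel @ u) / ev["speed"]

    def last_onset_before(site: str, t: float) -> float:
        best = -np.inf
        for ev in events:
            if ev["dropped"] or ev["t0"] > t + 1.0:
                continue
            o = ev_onset(ev, site)
            if o < t:
                best = max(best, o)
        return best

    tau_r = config.refractory_s
    n_stim = len(onsets)
    success = np.zeros(n_stim, dtype=bool)
    refractory = np.zeros(n_stim, dtype=bool)
    latency_ms = np.full(n_stim, np.nan)

    for k in range(n_stim):
        s, mod = float(onsets[k]), str(modalities[k])
        primary = PRIMARY_SITE[mod]
        last = last_onset_before(primary, s)
        inside = (s - last) < tau_r
        refractory[k] = inside
        p = config.p_refractory if inside else config.p_evoke
        if rng.random() >= p:
            continue
        mean = config.evoked_latency_ms[(mod, primary)]
        sd = config.evoked_latency_se_ms[(mod, primary)]
        if inside:
            sd *= config.refractory_latency_jitter_factor
        lat = max(float(rng.normal(mean, sd)), 1.0)
        t0 = s + lat / 1000.0
        # a spontaneous wave already rising between the stimulus and the
        # evoked onset absorbs the evoked wave (merge, keep its onset);
        # spontaneous waves due *after* the evoked onset are suppressed by
        # the refractory drop below
        merged_with = None
        for ev in events:
            if ev["dropped"] or abs(ev["t0"] - t0) > 2.0:
                continue
            if s < ev_onset(ev, primary) < t0 + 0.05:
                merged_with = ev
                break
        success[k] = True
        if merged_with is not None:
            merged_with["merged"] = True
            if merged_with["stim_index"] < 0:
                merged_with["stim_index"] = k
            latency_ms[k] = (ev_onset(merged_with, primary) - s) * 1000.0
            continue
        direction = float(wrap_angle(rng.normal(
            config.evoked_direction_rad[mod], config.direction_jitter_rad)))
        new_ev = {
            "t0": t0,
            "origin": (float(site_pos[primary][0]), float(site_pos[primary][1])),
            "speed": float(_truncated_normal(
                rng, config.speed_mean_mm_s, config.speed_sd_mm_s, 1)[0]),
            "direction": direction,
            "evoked": True, "merged": False, "stim_index": k,
            "modality": mod, "dropped": False,
        }
        events.append(new_ev)
        latency_ms[k] = lat
        # drop *later* spontaneous waves that would violate per-site spacing
        # (waves that already happened are history and are never removed)
        for ev in events:
            if (ev["dropped"] or ev["evoked"] or ev["t0"] <= t0
                    or ev["t0"] - t0 > tau_r + 1.0):
                continue
            if any(ev_onset(ev, site) - ev_onset(new_ev, site) < tau_r
                   for site in sites):
                ev["dropped"] = True

    kept = [ev for ev in events if not ev["dropped"]]
    kept.sort(key=lambda ev: ev["t0"])
    out = GroundTruth(config=config, geometry=geometry)
    out.event_time_s = np.asarray([ev["t0"] for ev in kept])
    out.origin_ap_mm = np.asarray([ev["origin"][0] for ev in kept])
    out.origin_ml_mm = np.asarray([ev["origin"][1] for ev in kept])
    out.speed_mm_s = np.asarray([ev["speed"] for ev in kept])
    out.direction_rad = np.asarray([ev["direction"] for ev in kept])
    out.evoked = np.asarray([ev["evoked"] for ev in kept], dtype=bool)
    out.merged = np.asarray([ev["merged"] for ev in kept], dtype=bool)
    out.stim_index = np.asarray([ev["stim_index"] for ev in kept], dtype=int)
    out.event_modality = np.asarray([ev["modality"] for ev in kept], dtype=object)
    out.stim_onset_s = onsets
    out.stim_modality = modalities
    out.stim_success = success
    out.stim_refractory = refractory
    out.stim_latency_ms = latency_ms
    out.warning = ground_truth.warning
    return out


# ----------------------------------------------------------------------
# rendering: photometry
# ----------------------------------------------------------------------

def render_photometry(
    ground_truth: GroundTruth,
    geometry: Optional[FieldGeometry] = None,
    config: Optional[SimConfig] = None,
    sites: Optional[Iterable[str]] = None,
):
    """Render raw fluorescence traces at each recording site.

    SWA traces are a constant baseline plus one calcium kernel per wave at
    that site's onset time; PA traces are band-limited fluctuations around
    ``pa_band_hz`` plus short-latency evoked transients confined to the
    stimulated modality's primary site.  Gaussian noise of SD
    ``noise_sd * amplitude`` (relative to baseline) is added.

    Returns
    -------
    dict mapping site name -> :class:`cortexwave.photometry.PhotometryTrace`
    (raw fluorescence in arbitrary units; normalize with ``normalize_dff``).
    """
    from .photometry import PhotometryTrace

    config = config or ground_truth.config
    geometry = geometry or ground_truth.geometry
    if config.fs_trace_hz < 100:
        raise ValueError("fs_trace_hz must be >= 100 for photometry rendering")
    sites = list(sites) if sites is not None else list(geometry.sites)
    fs = config.fs_trace_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    f0 = config.baseline_fluorescence
    out = {}
    for idx, site in enumerate(sites):
        rng = np.random.default_rng([config.seed, 201, idx])
        dff = np.zeros(n)
        if config.state == "SWA":
            onsets = ground_truth.site_onsets(site)
            _add_kernels(dff, onsets, fs, config.amplitude,
                         config.tau_rise_s, config.tau_decay_s)
        else:
            dff += config.pa_fluct_amplitude * _bandlimited_noise(
                rng, n, fs, (config.pa_band_hz - config.pa_band_halfwidth_hz,
                             config.pa_band_hz + config.pa_band_halfwidth_hz))
            if ground_truth.stim_onset_s is not None:
                for s, mod in zip(ground_truth.stim_onset_s,
                                  ground_truth.stim_modality):
                    if PRIMARY_SITE[str(mod)] != site:
                        continue
                    lat = max(rng.normal(config.pa_evoked_latency_ms,
                                         config.pa_evoked_latency_sd_ms), 1.0)
                    _add_kernels(dff, np.array([s + lat / 1000.0]), fs,
                                 config.pa_evoked_amplitude,
                                 config.pa_tau_rise_s, config.pa_tau_decay_s)
        noise = config.noise_sd * config.amplitude * rng.standard_normal(n)
        raw = f0 * (1.0 + dff + noise)
        out[site] = PhotometryTrace(samples=raw, fs_hz=fs, site=site,
                                    state_label=config.state)
    return out


def _add_kernels(dff: np.ndarray, onsets: np.ndarray, fs: float,
                 amplitude: float, tau_rise: float, tau_decay: float) -> None:
    """Add ``amplitude * kernel(t - onset)`` in-place for each onset."""
    n = len(dff)
    span = int(np.ceil((tau_rise * 6 + tau_decay * 8) * fs))
    if span >= n:
        warnings.warn("calcium kernel longer than trace; response truncated")
        span = n
    rel = np.arange(span) / fs
    k = amplitude * calcium_kernel(rel, tau_rise, tau_decay)
    for o in np.atleast_1d(onsets):
        i0 = int(np.ceil(o * fs))
        if i0 >= n:
            continue
        frac = i0 / fs - o  # sub-sample offset of first sample after onset
        kk = amplitude * calcium_kernel(rel + frac, tau_rise, tau_decay)
        i1 = min(i0 + span, n)
        lo = max(i0, 0)
        dff[lo:i1] += kk[lo - i0:i1 - i0]


# ----------------------------------------------------------------------
# rendering: wide-field movies
# ----------------------------------------------------------------------

def render_widefield(
    ground_truth: GroundTruth,
    geometry: Optional[FieldGeometry] = None,
    config: Optional[SimConfig] = None,
):
    """Render a wide-field fluorescence movie from the ground truth.

    SWA waves are plane wavefronts: pixel activation time equals
    ``t0 + (p - origin) . u / speed``; spontaneous waves span the whole
    field, evoked responses are restricted to a near-disc of the configured
    state- and modality-specific area around the initiation site.  PA
    ongoing activity is a sum of smooth spatial modes with slow band-limited
    time courses (never fully active nor fully silent); evoked PA responses
    are short transients on the confined disc.  Per-pixel i.i.d. Gaussian
    noise is added.

    Returns a :class:`cortexwave.widefield.Movie` of raw intensities.
    """
    from .widefield import Movie

    config = config or ground_truth.config
    geometry = geometry or ground_truth.geometry
    if config.frame_rate_hz < 10:
        raise ValueError("frame_rate_hz must be >= 10")
    rate = config.frame_rate_hz
    n_frames = int(round(config.duration_s * rate))
    if n_frames < 2:
        raise ValueError("duration too short for a movie")
    H, W = geometry.shape
    t_f = np.arange(n_frames) / rate
    ap, ml = geometry.pixel_grid()
    rng = np.random.default_rng([config.seed, 301])
    sig = np.zeros((n_frames, H, W), dtype=np.float64)

    if config.state == "SWA":
        for i in range(ground_truth.n_events):
            u = unit_vector(ground_truth.direction_rad[i])
            t_act = (ground_truth.event_time_s[i]
                     + ((ap - ground_truth.origin_ap_mm[i]) * u[0]
                        + (ml - ground_truth.origin_ml_mm[i]) * u[1])
                     / ground_truth.speed_mm_s[i])
            if ground_truth.evoked[i]:
                mod = str(ground_truth.event_modality[i])
                area = config.evoked_area_mm2[(config.state, mod)]
                support = geometry.disc_mask(ground_truth.origin_ap_mm[i],
                                             ground_truth.origin_ml_mm[i], area)
            else:
                support = np.ones((H, W), dtype=bool)
            _add_wave(sig, t_f, t_act, support, config)
    else:
        sig += _pa_background(rng, t_f, geometry, config)
        if ground_truth.stim_onset_s is not None:
            for s, mod in zip(ground_truth.stim_onset_s, ground_truth.stim_modality):
                mod = str(mod)
                centre = geometry.site_position(PRIMARY_SITE[mod])
                area = config.evoked_area_mm2[(config.state, mod)]
                support = geometry.disc_mask(centre[0], centre[1], area)
                lat = max(rng.normal(config.pa_evoked_latency_ms,
                                     config.pa_evoked_latency_sd_ms), 1.0) / 1000.0
                t_act = np.full((H, W), s + lat)
                _add_wave(sig, t_f, t_act, support, config,
                          amplitude=config.pa_evoked_amplitude,
                          tau_rise=config.pa_tau_rise_s,
                          tau_decay=config.pa_tau_decay_s)

    noise = config.noise_sd * config.amplitude * rng.standard_normal(sig.shape)
    frames = (config.baseline_fluorescence * (1.0 + sig + noise)).astype(np.float32)
    return Movie(frames=frames, frame_rate_hz=rate, geometry=geometry,
                 midline_aligned=True)


def _add_wave(sig: np.ndarray, t_f: np.ndarray, t_act: np.ndarray,
              support: np.ndarray, config: SimConfig,
              amplitude: Optional[float] = None,
              tau_rise: Optional[float] = None,
              tau_decay: Optional[float] = None) -> None:
    amplitude = config.amplitude if amplitude is None else amplitude
    tau_rise = config.tau_rise_s if tau_rise is None else tau_rise
    tau_decay = config.tau_decay_s if tau_decay is None else tau_decay
    rate = 1.0 / (t_f[1] - t_f[0]) if len(t_f) > 1 else 1.0
    lo_t = float(t_act[support].min()) if support.any() else np.inf
    hi_t = float(t_act[support].max()) + 6 * tau_rise + 8 * tau_decay
    f0 = max(int(np.floor(lo_t * rate)), 0)
    f1 = min(int(np.ceil(hi_t * rate)) + 1, len(t_f))
    if f1 <= f0:
        return
    dt = t_f[f0:f1, None] - t_act[support][None, :]
    sig[f0:f1, support] += amplitude * calcium_kernel(dt, tau_rise, tau_decay)


def _pa_background(rng: np.random.Generator, t_f: np.ndarray,
                   geometry: FieldGeometry, config: SimConfig,
                   n_modes: int = 6, mode_sigma_mm: float = 1.2) -> np.ndarray:
    """Smooth spatial modes with slow band-limited time courses."""
    n_frames = len(t_f)
    rate = 1.0 / (t_f[1] - t_f[0])
    band = (0.2, min(3.0, 0.4 * rate))
    ap, ml = geometry.pixel_grid()
    sig = np.zeros((n_frames,) + geometry.shape)
    # global mode drives the field-of-view mean fluctuation
    sig += (config.pa_fluct_amplitude
            * _bandlimited_noise(rng, n_frames, rate, band))[:, None, None]
    for _ in range(n_modes):
        c_ap = rng.uniform(-geometry.fov_ap_mm, 0.0)
        c_ml = rng.uniform(0.0, geometry.fov_ml_mm)
        blob = np.exp(-((ap - c_ap) ** 2 + (ml - c_ml) ** 2)
                      / (2 * mode_sigma_mm**2))
        course = config.pa_fluct_amplitude * _bandlimited_noise(
            rng, n_frames, rate, band)
        sig += course[:, None, None] * blob[None, :, :]
    return sig


# ----------------------------------------------------------------------
# rendering: LFP
# ----------------------------------------------------------------------

def render_lfp(
    ground_truth: GroundTruth,
    config: Optional[SimConfig] = None,
    site: str = "V1",
):
    """Render an LFP-like trace at one site.

    SWA: a low noise floor with burst-gated broadband noise during each
    wave (burst envelope is a fast double-exponential at the site's wave
    onset).  PA: a continuous narrowband oscillation around ``pa_band_hz``
    over low-passed background noise.  In both states each stimulus whose
    primary sensory site is ``site`` adds a brief gamma-band packet locked
    to the stimulus (the state-independent primary sensory response).
    """
    from .photometry import PhotometryTrace

    config = config or ground_truth.config
    fs = config.fs_trace_hz
    if fs < 500:
        raise ValueError("fs_trace_hz must be >= 500 for LFP rendering")
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    site_idx = list(ground_truth.geometry.sites).index(site)
    rng = np.random.default_rng([config.seed, 401, site_idx])

    x = config.lfp_noise_floor * config.lfp_burst_amp * rng.standard_normal(n)
    if config.state == "SWA":
        env = np.zeros(n)
        _add_kernels(env, ground_truth.site_onsets(site), fs, 1.0,
                     config.lfp_tau_rise_s, config.lfp_tau_decay_s)
        burst = _bandlimited_noise(rng, n, fs, config.lfp_burst_band)
        x += config.lfp_burst_amp * env * burst
    else:
        x += config.lfp_pa_narrowband_amp * _bandlimited_noise(
            rng, n, fs, (config.pa_band_hz - 2.0, config.pa_band_hz + 2.0))
        x += config.lfp_pa_broadband_amp * _bandlimited_noise(
            rng, n, fs, (0.5, 50.0))
    if ground_truth.stim_onset_s is not None:
        packet_len = int(round(0.08 * fs))
        win = np.hanning(packet_len)
        gamma = _bandlimited_noise(rng, n, fs, config.lfp_gamma_band)
        for s, mod in zip(ground_truth.stim_onset_s, ground_truth.stim_modality):
            if PRIMARY_SITE[str(mod)] != site:
                continue
            i0 = int(round((s + 0.005) * fs))
            i1 = min(i0 + packet_len, n)
            if i0 < n:
                x[i0:i1] += (config.lfp_gamma_amp
                             * win[:i1 - i0] * gamma[i0:i1])
    return PhotometryTrace(samples=x, fs_hz=fs, site=site,
                           state_label=config.state, kind="lfp")
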