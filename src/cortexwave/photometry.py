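"""Fibre-photometry trace analysis.

Normalization to df/f, Gaussian low-pass filtering, threshold-based
slow-wave event detection, stimulus-locked latency estimation with
shuffled-onset controls, and inter-regional delay / lead-lag structure.

The event detector operationalizes "event detection" as an upward crossing
of ``baseline_mean + k * baseline_SD`` sustained for a minimum duration,
with the baseline statistics estimated from an iteratively refined
sub-threshold mask so that the events themselves do not inflate the
baseline.  Detected onsets are refined by walking back from the detection
threshold to the last sample within one baseline SD, which removes most of
the rise-time bias of a high threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .synthgen import StimulusTrain

__all__ = [
    "PhotometryTrace",
    "EventList",
    "normalize_dff",
    "find_quiet_baseline",
    "lowpass_gaussian",
    "detect_events",
    "response_latency",
    "shuffle_onsets",
    "cross_correlogram",
    "interregion_delays",
    "DegenerateBaselineError",
    "NoBaselineError",
    "UndefinedCorrelationError",
]


class DegenerateBaselineError(ValueError):
    """Baseline mean is non-positive; df/f is undefined."""


class NoBaselineError(ValueError):
    """No sub-threshold samples; baseline statistics cannot be estimated."""


class UndefinedCorrelationError(ValueError):
    """Zero-variance input; correlation is undefined."""


@dataclass
class PhotometryTrace:
    """A single-site time series (calcium photometry or LFP).

    ``samples`` are raw fluorescence (a.u.) or df/f depending on
    processing stage; ``kind`` distinguishes calcium from LFP traces.
    """

    samples: np.ndarray
    fs_hz: float = 2000.0
    site: str = "S1"
    state_label: str = "unknown"
    kind: str = "calcium"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs_hz

    def copy_with(self, samples: np.ndarray) -> "PhotometryTrace":
        return PhotometryTrace(samples=samples, fs_hz=self.fs_hz,
                               site=self.site, state_label=self.state_label,
                               kind=self.kind)


@dataclass
class EventList:
    """Detected (or ground-truth) events at one site."""

    onset_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitude: np.ndarray = field(default_factory=lambda: np.empty(0))
    duration_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    site: str = ""

    def __post_init__(self) -> None:
        for name in ("onset_s", "peak_s", "amplitude", "duration_s"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.onset_s) > 1 and not np.all(np.diff(self.onset_s) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if np.any(self.peak_s < self.onset_s):
            raise ValueError("peak_s must be >= onset_s")
        if len(self.duration_s) and np.any(self.duration_s <= 0):
            raise ValueError("duration_s must be positive")

    def __len__(self) -> int:
        return len(self.onset_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onset_s, "peak_s": self.peak_s,
            "amplitude": self.amplitude, "duration_s": self.duration_s,
            "site": self.site,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site: str = "") -> "EventList":
        site = site or (str(df["site"].iloc[0]) if "site" in df and len(df) else "")
        return cls(onset_s=df["onset_s"].to_numpy(),
                   peak_s=df["peak_s"].to_numpy(),
                   amplitude=df["amplitude"].to_numpy(),
                   duration_s=df["duration_s"].to_numpy(), site=site)


# ----------------------------------------------------------------------
# normalization and filtering
# ----------------------------------------------------------------------

def normalize_dff(trace: PhotometryTrace,
                  baseline_window_s: Tuple[float, float]) -> PhotometryTrace:
    """Express a raw trace as relative change df/f = raw / mean(baseline) - 1.

    ``baseline_window_s`` is a (start, end) interval, at least 0.5 s long,
    lying within the trace — typically a manually chosen quiet second.
    """
    t0, t1 = baseline_window_s
    if t1 - t0 < 0.5:
        raise ValueError("baseline window must be at least 0.5 s long")
    if t0 < 0 or t1 > trace.duration_s:
        raise ValueError("baseline window must lie within the trace")
    i0, i1 = int(round(t0 * trace.fs_hz)), int(round(t1 * trace.fs_hz))
    f0 = trace.samples[i0:i1].mean()
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"baseline mean {f0:.4g} is not positive; df/f undefined")
    return trace.copy_with(trace.samples / f0 - 1.0)


def find_quiet_baseline(trace: PhotometryTrace,
                        length_s: float = 1.0) -> Tuple[float, float]:
    """Locate the quietest window of a trace for df/f normalization.

    Returns the (start, end) of the ``length_s`` window with the lowest
    mean level — an automatic stand-in for the conventional manually
    chosen second of baseline.
    """
    n_win = int(round(length_s * trace.fs_hz))
    if n_win < 2 or n_win > len(trace.samples):
        raise ValueError("baseline window must fit inside the trace")
    rolling = ndimage.uniform_filter1d(trace.samples, size=n_win,
                                       mode="nearest")
    centre = int(np.argmin(rolling))
    start = np.clip(centre - n_win // 2, 0, len(trace.samples) - n_win)
    return start / trace.fs_hz, (start + n_win) / trace.fs_hz


def gaussian_sigma_for_cutoff(cutoff_hz: float) -> float:
    """Gaussian kernel SD (s) whose transfer function is -3 dB at cutoff.

    ``|H(f)| = exp(-2 pi^2 sigma^2 f^2)``; solving |H(fc)| = 1/sqrt(2)
    gives ``sigma = sqrt(ln 2) / (2 pi fc)``.
    """
    return float(np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz))


def lowpass_gaussian(trace: PhotometryTrace, cutoff_hz: float = 20.0) -> PhotometryTrace:
    """Zero-phase Gaussian low-pass with -3 dB point at ``cutoff_hz``."""
    if cutoff_hz >= trace.fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sigma = gaussian_sigma_for_cutoff(cutoff_hz) * trace.fs_hz
    smoothed = ndimage.gaussian_filter1d(trace.samples, sigma, mode="nearest")
    return trace.copy_with(smoothed)


# ----------------------------------------------------------------------
# event detection
# ----------------------------------------------------------------------

def _baseline_stats(x: np.ndarray, n_bins: int = 200) -> Tuple[float, float]:
    """Baseline mean and noise SD from the amplitude-histogram mode.

    Calcium waves only deflect the trace upwards, so the histogram mode
    locates the silent-period level at any event occupancy, and the
    samples *below* the mode are pure baseline noise: their RMS distance
    from the mode estimates the noise SD (one half of the symmetric
    noise distribution).  A second pass refines the mode as the mean of
    the +/- 2 SD core.
    """
    lo, hi = np.percentile(x, [0.5, 99.5])
    if hi - lo <= 0:
        return float(x[0]), 0.0
    sel = x[(x >= lo) & (x <= hi)]
    hist, edges = np.histogram(sel, bins=n_bins)
    i = int(np.argmax(hist))
    m = 0.5 * (edges[i] + edges[i + 1])
    for _ in range(2):
        below = x[x <= m]
        if len(below) == 0:
            raise NoBaselineError("no sub-baseline samples (saturated trace)")
        s = float(np.sqrt(np.mean((below - m) ** 2)))
        if s == 0:
            return m, 0.0
        core = x[(x >= m - 2 * s) & (x <= m + s)]
        if len(core) == 0:
            break
        m = float(np.median(core))
    return m, s


def detect_events(trace: PhotometryTrace, k_sd: float = 3.0,
                  min_duration_s: float = 0.2,
                  min_separation_s: float = 1.0,
                  split_prominence_sd: float = 10.0,
                  onset_refine_max_s: float = 0.15) -> EventList:
    """Detect slow-wave events as sustained threshold crossings.

    The trace should already be df/f and low-pass filtered.  An event
    starts where the signal crosses ``baseline_mean + k_sd * baseline_SD``
    and remains above threshold for at least ``min_duration_s``; events
    separated by less than ``min_separation_s`` are merged.  Because a
    wave arriving within a couple of seconds of the previous one rides on
    its decay tail (the signal never returns to baseline between them), a
    supra-threshold run containing several peaks of prominence at least
    ``split_prominence_sd`` baseline SDs is split at the valleys between
    peaks, one event per peak.  Reported onsets are refined to the last
    sample within one baseline SD before the crossing (bounded walk-back),
    or to the preceding valley for split events.
    """
    x = trace.samples
    fs = trace.fs_hz
    m, s = _baseline_stats(x)
    thresh = m + k_sd * s
    above = x > thresh
    if not above.any():
        return EventList(site=trace.site)

    # run-length encode the supra-threshold mask
    idx = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    run_starts, run_ends = idx[::2], idx[1::2]

    # merge runs separated by less than min_separation_s
    merged: list[tuple[int, int]] = []
    for a, b in zip(run_starts, run_ends):
        if merged and (a - merged[-1][1]) / fs < min_separation_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    onset_idx, peak_idx, amp, dur = [], [], [], []
    max_back = int(round(onset_refine_max_s * fs))
    for a, b in merged:
        if (b - a) / fs < min_duration_s:
            continue
        seg = x[a:b]
        pk, _ = sps.find_peaks(seg, prominence=split_prominence_sd * s,
                               distance=max(int(min_separation_s * fs), 1))
        if len(pk) == 0:
            pk = np.array([int(np.argmax(seg))])
        # noise excursions can sustain long low runs; require event peaks
        # to clear the same prominence floor above baseline
        pk = pk[x[a + pk] - m >= split_prominence_sd * s]
        # event boundaries: run start, valleys between peaks, run end
        bounds = [0]
        for p1, p2 in zip(pk[:-1], pk[1:]):
            bounds.append(p1 + int(np.argmin(seg[p1:p2])))
        bounds.append(b - a)
        for j, p in enumerate(pk):
            # onset refined by back-extrapolating the steepest-rise tangent
            # to the local pre-peak floor; insensitive to baseline-SD
            # contamination on high-occupancy traces
            win_lo = a + bounds[j] if j > 0 else max(a - max_back, 0)
            win = x[win_lo:a + p]
            o = win_lo
            step = max(int(round(0.005 * fs)), 1)  # 5-ms slope estimator
            if len(win) > step + 1:
                d1 = win[step:] - win[:-step]
                i_star = int(np.argmax(d1))
                slope = d1[i_star] / step
                if slope > 0:
                    back = (win[i_star] - win.min()) / slope
                    o = win_lo + int(np.clip(round(i_star - back),
                                             0, len(win) - 1))
                else:
                    o = win_lo + int(np.argmin(win))
            onset_idx.append(o)
            peak_idx.append(a + p)
            amp.append(x[a + p] - m)
            dur.append((bounds[j + 1] - bounds[j]) / fs)
    if not onset_idx:
        return EventList(site=trace.site)
    return EventList(onset_s=np.asarray(onset_idx) / fs,
                     peak_s=np.asarray(peak_idx) / fs,
                     amplitude=np.asarray(amp),
                     duration_s=np.asarray(dur), site=trace.site)


# ----------------------------------------------------------------------
# stimulus-locked latencies
# ----------------------------------------------------------------------

def response_latency(trace: PhotometryTrace, stimuli: StimulusTrain,
                     mode: str, window_s: float = 2.0,
                     events: Optional[EventList] = None,
                     **detect_kwargs) -> Tuple[np.ndarray, np.ndarray]:
    """Per-stimulus response latency (s).

    ``mode="swa_onset"``: time from stimulus to the next detected event
    onset within ``window_s`` (events detected on the trace unless given).
    ``mode="pa_peak"``: time from stimulus to the maximum amplitude within
    the post-stimulus window.

    Returns
    -------
    latencies : array of seconds, NaN where no response was found.
    skipped : boolean array, True for stimuli too close to the trace end
        (their latency is NaN and they should be excluded from pooling).
    """
    if mode not in ("swa_onset", "pa_peak"):
        raise ValueError("mode must be 'swa_onset' or 'pa_peak'")
    onsets = stimuli.onsets_s
    lat = np.full(len(onsets), np.nan)
    skipped = onsets + window_s > trace.duration_s
    if mode == "swa_onset":
        if events is None:
            events = detect_events(trace, **detect_kwargs)
        ev = events.onset_s
        for i, s in enumerate(onsets):
            if skipped[i]:
                continue
            j = np.searchsorted(ev, s, side="left")
            if j < len(ev) and ev[j] - s <= window_s:
                lat[i] = ev[j] - s
    else:
        fs = trace.fs_hz
        for i, s in enumerate(onsets):
            if skipped[i]:
                continue
            i0 = int(np.ceil(s * fs))
            i1 = min(int(np.floor((s + window_s) * fs)) + 1, len(trace.samples))
            if i1 <= i0:
                skipped[i] = True
                continue
            lat[i] = (i0 + int(np.argmax(trace.samples[i0:i1]))) / fs - s
    return lat, skipped


def shuffle_onsets(stimuli: StimulusTrain, jitter_range_s: float = 2.0,
                   seed: Optional[int] = None) -> StimulusTrain:
    """Jitter each stimulus onset uniformly within a centred range.

    Each onset moves by Uniform(-jitter_range_s/2, +jitter_range_s/2) —
    i.e. uniformly within a total range of ``jitter_range_s`` centred on
    the true onset — independently per stimulus; the count is preserved
    and the result re-sorted.
    """
    if jitter_range_s <= 0:
        raise ValueError("jitter_range_s must be positive")
    rng = np.random.default_rng(seed)
    half = jitter_range_s / 2.0
    jittered = np.sort(stimuli.onsets_s
                       + rng.uniform(-half, half, size=len(stimuli)))
    # break exact ties (probability-zero, but keep the invariant)
    for i in range(1, len(jittered)):
        if jittered[i] <= jittered[i - 1]:
            jittered[i] = jittered[i - 1] + 1e-9
    return StimulusTrain(onsets_s=jittered, modality=stimuli.modality,
                         pulse_ms=stimuli.pulse_ms,
                         amplitude_ma=stimuli.amplitude_ma,
                         description=stimuli.description + " (shuffled)")


# ----------------------------------------------------------------------
# inter-regional structure
# ----------------------------------------------------------------------

def cross_correlogram(trace_a: PhotometryTrace, trace_b: PhotometryTrace,
                      max_lag_s: float) -> Tuple[np.ndarray, np.ndarray, float]:
    """Normalized cross-correlation over lags in [-max_lag, +max_lag].

    Sign convention: a positive peak lag means ``trace_a`` leads
    ``trace_b`` (b is a delayed copy of a).

    Returns ``(lags_s, correlation, peak_lag_s)``.
    """
    if trace_a.fs_hz != trace_b.fs_hz:
        raise ValueError("traces must share a sampling rate")
    n = min(len(trace_a.samples), len(trace_b.samples))
    if n / trace_a.fs_hz < 2 * max_lag_s:
        raise ValueError("overlapping duration must be >= 2 * max_lag_s")
    fs = trace_a.fs_hz
    a = trace_a.samples[:n] - trace_a.samples[:n].mean()
    b = trace_b.samples[:n] - trace_b.samples[:n].mean()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedCorrelationError("zero-variance input")
    # c[lag] = sum_t b(t + lag) a(t): peak at +delta when b(t) = a(t - delta)
    c = sps.correlate(b, a, mode="full", method="fft") / (n * sa * sb)
    lags = np.arange(-(n - 1), n) / fs
    sel = np.abs(lags) <= max_lag_s
    lags, c = lags[sel], c[sel]
    peak_lag = float(lags[int(np.argmax(c))])
    return lags, c, peak_lag


def interregion_delays(events_a: EventList, events_b: EventList,
                       match_window_s: float = 1.0
                       ) -> Tuple[np.ndarray, float]:
    """Match events across two sites and compute per-pair onset delays.

    Pairs are formed greedily by nearest onset within ``match_window_s``
    (each event used at most once, smallest |delay| first).  The delay of
    a pair is ``onset_b - onset_a``, so positive delays mean site *a*
    leads.  Returns ``(delays_s, leader_fraction_a)``; with no matches the
    delays are empty and the fraction NaN (a warning is emitted).
    """
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both event lists must be non-empty")
    a, b = events_a.onset_s, events_b.onset_s
    cand = [(abs(b[j] - a[i]), i, j)
            for i in range(len(a))
            for j in range(len(b)) if abs(b[j] - a[i]) <= match_window_s]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a[i], b[j] - a[i]))
    if not pairs:
        warnings.warn("no events matched within the window")
        return np.empty(0), float("nan")
    pairs.sort()
    delays = np.asarray([d for _, d in pairs])
    return delays, float(np.mean(delays > 0))
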