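"""Wide-field movie analysis: triggered averages, latency maps, response
areas, gradient-based velocity fields, and activation-probability
distributions with permutation testing.

The propagation estimator follows the response-time-map approach: each
pixel's onset latency is the first post-stimulus threshold crossing
(3.5 SD of the averaged pre-stimulus signal), and the spatial gradient of
the (median-smoothed) latency map gives per-pixel slowness ``g = grad t``
in s/mm, hence ``speed = 1/|g|`` and propagation direction ``atan2(g)``
pointing from early to late pixels.  Latencies are refined by linear
interpolation between the last sub-threshold and first supra-threshold
frame; frame-quantized latencies make the gradient degenerate at typical
frame rates (a wave crosses the field in only a few frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .geometry import FieldGeometry, wrap_angle

__all__ = [
    "Movie",
    "TriggeredAverage",
    "LatencyMap",
    "VelocityField",
    "ActivationHistogram",
    "dff_movie",
    "stimulus_triggered_average",
    "onset_latency_map",
    "response_area",
    "velocity_field",
    "mean_velocity_vector",
    "activation_distribution",
    "compare_distributions_permutation",
    "EmptyAverageError",
    "DegenerateMapError",
    "DegenerateFieldError",
    "DegenerateNormalizationError",
]


class EmptyAverageError(ValueError):
    """No usable stimulus window; the triggered average is empty."""


class DegenerateMapError(ValueError):
    """Latency map has too few valid pixels for a gradient."""


class DegenerateFieldError(ValueError):
    """Velocity field contains no valid vectors."""


class DegenerateNormalizationError(ValueError):
    """Constant trace; activation normalization is undefined."""


@dataclass
class Movie:
    """T x H x W intensity stack with frame rate and field geometry."""

    frames: np.ndarray
    frame_rate_hz: float
    geometry: FieldGeometry
    midline_aligned: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a T x H x W stack with T >= 2")
        if self.frames.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match "
                f"geometry {self.geometry.shape}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class TriggeredAverage:
    """Stimulus-aligned average df/f stack (percent), t = 0 at onset frame."""

    frames: np.ndarray          # T x H x W, percent df/f
    t_s: np.ndarray             # time of each frame relative to stimulus
    frame_rate_hz: float
    geometry: FieldGeometry
    n_stimuli: int = 0


@dataclass
class LatencyMap:
    """Per-pixel response-onset latency (s) relative to the stimulus."""

    latency_s: np.ndarray       # H x W, NaN where no onset
    geometry: FieldGeometry

    def __post_init__(self) -> None:
        lat = np.asarray(self.latency_s, dtype=float)
        if np.any(lat[np.isfinite(lat)] < 0):
            raise ValueError("latencies must be nonnegative")
        self.latency_s = lat


@dataclass
class VelocityField:
    """Per-pixel propagation speed (mm/s) and direction (rad)."""

    speed_mm_s: np.ndarray
    direction_rad: np.ndarray
    valid: np.ndarray
    geometry: FieldGeometry

    def vectors(self) -> Tuple[np.ndarray, np.ndarray]:
        """Valid (direction, speed) pairs as flat arrays."""
        v = self.valid
        return self.direction_rad[v], self.speed_mm_s[v]


@dataclass
class ActivationHistogram:
    """Probability mass of normalized activation over [0, 1]."""

    bin_edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < 0):
            raise ValueError("masses must be nonnegative")
        if abs(self.mass.sum() - 1.0) > 1e-8:
            raise ValueError("masses must sum to 1")


# ----------------------------------------------------------------------
# df/f and triggered averages
# ----------------------------------------------------------------------

def _reference_frame_index(onset_s: float, rate: float) -> int:
    """Index of the last frame strictly before the stimulus onset."""
    return int(np.ceil(onset_s * rate - 1e-9)) - 1


def dff_movie(movie: Movie, stimulus_onset_s: float) -> Movie:
    """Percent df/f with the frame before stimulus onset as reference.

    Per pixel, ``dff_t = 100 * (F_t - F0) / F0`` with ``F0`` the frame
    immediately preceding the stimulus.  Pixels with ``F0 <= 0`` are
    masked to NaN with a warning.
    """
    ref = _reference_frame_index(stimulus_onset_s, movie.frame_rate_hz)
    if ref < 0:
        raise ValueError("stimulus onset must map to frame index >= 1")
    f0 = movie.frames[ref].astype(float)
    bad = f0 <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels with nonpositive reference; masked")
        f0 = np.where(bad, np.nan, f0)
    dff = 100.0 * (movie.frames.astype(float) - f0[None]) / f0[None]
    return Movie(frames=dff, frame_rate_hz=movie.frame_rate_hz,
                 geometry=movie.geometry, midline_aligned=movie.midline_aligned)


def stimulus_triggered_average(
    movie: Movie,
    stimuli,
    window_s: Tuple[float, float] = (-1.0, 3.0),
) -> TriggeredAverage:
    """Average df/f segments aligned at stimulus onset.

    Each stimulus contributes a segment normalized to its own pre-stimulus
    reference frame; segments whose window falls outside the movie are
    skipped.  ``stimuli`` may be a StimulusTrain or an array of onsets.
    """
    onsets = np.asarray(getattr(stimuli, "onsets_s", stimuli), dtype=float)
    rate = movie.frame_rate_hz
    w0, w1 = window_s
    off0, off1 = int(round(w0 * rate)), int(round(w1 * rate))
    if off1 <= off0:
        raise ValueError("empty averaging window")
    acc = None
    count = 0
    for s in onsets:
        ref = _reference_frame_index(s, rate)
        onset_frame = ref + 1
        i0, i1 = onset_frame + off0, onset_frame + off1
        if ref < 0 or i0 < 0 or i1 > movie.n_frames:
            continue
        f0 = movie.frames[ref].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = 100.0 * (movie.frames[i0:i1].astype(float) - f0[None]) / f0[None]
        acc = seg if acc is None else acc + seg
        count += 1
    if count == 0:
        raise EmptyAverageError("no stimulus with a full window in bounds")
    t_s = np.arange(off0, off1) / rate
    return TriggeredAverage(frames=acc / count, t_s=t_s, frame_rate_hz=rate,
                            geometry=movie.geometry, n_stimuli=count)


# ----------------------------------------------------------------------
# latency maps, areas, velocity
# ----------------------------------------------------------------------

def _prestim_threshold(sta: TriggeredAverage, prestim_window_s: float,
                       k_sd: float) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel threshold = prestim mean + k_sd * prestim SD."""
    pre = (sta.t_s < 0) & (sta.t_s >= -prestim_window_s)
    if pre.sum() < 3:
        raise ValueError("prestimulus window must contain >= 3 frames")
    pre_frames = sta.frames[pre]
    m = pre_frames.mean(axis=0)
    sd = pre_frames.std(axis=0, ddof=1)
    thresh = m + k_sd * sd
    degenerate = sd == 0
    return np.where(degenerate, np.nan, thresh), degenerate


def onset_latency_map(sta: TriggeredAverage, prestim_window_s: float = 1.0,
                      k_sd: float = 3.5, interpolate: bool = True) -> LatencyMap:
    """Per-pixel onset latency from the first supra-threshold frame.

    A pixel's onset is the first post-stimulus frame whose df/f exceeds
    ``prestim_mean + k_sd * prestim_SD``.  With ``interpolate=True``
    (default) the crossing time is linearly interpolated between the
    preceding frame and the crossing frame, giving sub-frame resolution.
    Pixels that never cross, or with zero pre-stimulus variance, are NaN.
    """
    thresh, _ = _prestim_threshold(sta, prestim_window_s, k_sd)
    post = sta.t_s >= 0
    post_idx = np.flatnonzero(post)
    frames = sta.frames
    above = frames[post_idx] > thresh[None]
    crossed = above.any(axis=0)
    first = np.argmax(above, axis=0)  # index into post_idx

    H, W = frames.shape[1:]
    lat = np.full((H, W), np.nan)
    rows, cols = np.nonzero(crossed & np.isfinite(thresh))
    for r, c in zip(rows, cols):
        j = post_idx[first[r, c]]
        t_cross = sta.t_s[j]
        if interpolate and j > 0:
            prev, cur = frames[j - 1, r, c], frames[j, r, c]
            if np.isfinite(prev) and cur > prev:
                frac = (thresh[r, c] - prev) / (cur - prev)
                frac = float(np.clip(frac, 0.0, 1.0))
                t_cross = sta.t_s[j - 1] + frac * (sta.t_s[j] - sta.t_s[j - 1])
        lat[r, c] = max(t_cross, 0.0)
    return LatencyMap(latency_s=lat, geometry=sta.geometry)


def response_area(sta_or_latency: Union[TriggeredAverage, LatencyMap],
                  window_s: Tuple[float, float] = (1.0, 2.0),
                  geometry: Optional[FieldGeometry] = None,
                  k_sd: float = 3.5, prestim_window_s: float = 1.0,
                  mode: str = "simultaneous") -> float:
    """Response area (mm^2) from supra-threshold pixel counts.

    For a triggered average, a pixel counts as activated in a frame when
    its df/f exceeds the 3.5-SD pre-stimulus threshold; the area is the
    maximum simultaneous count over frames within ``window_s``
    (``mode="simultaneous"``, default) or the count of pixels active in
    any frame of the window (``mode="cumulative"``), times the pixel
    area.  For a latency map, the count of pixels with onset at or before
    the window end is used.
    """
    if mode not in ("simultaneous", "cumulative"):
        raise ValueError("mode must be 'simultaneous' or 'cumulative'")
    w0, w1 = window_s
    if isinstance(sta_or_latency, LatencyMap):
        geom = geometry or sta_or_latency.geometry
        count = int(np.nansum(sta_or_latency.latency_s <= w1))
        return count * geom.pixel_pitch_mm**2
    sta = sta_or_latency
    geom = geometry or sta.geometry
    thresh, _ = _prestim_threshold(sta, prestim_window_s, k_sd)
    sel = (sta.t_s >= w0) & (sta.t_s <= w1)
    if not sel.any():
        raise ValueError("window outside the averaged stack")
    active = sta.frames[sel] > thresh[None]
    if mode == "simultaneous":
        count = int(active.sum(axis=(1, 2)).max())
    else:
        count = int(active.any(axis=0).sum())
    return count * geom.pixel_pitch_mm**2


def _nanmedian_filter(x: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return x.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ndimage.generic_filter(x, np.nanmedian, size=size, mode="nearest")


def velocity_field(latency_map: LatencyMap,
                   geometry: Optional[FieldGeometry] = None,
                   smooth_px: int = 3,
                   smooth_mean_px: int = 0,
                   max_speed_mm_s: float = 1000.0) -> VelocityField:
    """Propagation velocity from the spatial gradient of a latency map.

    After median smoothing the latency map (and optionally mean smoothing
    over ``smooth_mean_px``), the gradient ``g = grad t`` (s/mm, computed
    by central differences in stereotaxic AP/ML axes) gives
    ``speed = 1/|g|`` and direction ``atan2(g_ml, g_ap)`` pointing from
    early towards late pixels — the propagation direction.  Pixels whose
    implied speed exceeds ``max_speed_mm_s`` (near-simultaneous
    activation, no directional information) or that touch NaN neighbours
    are marked invalid.

    On latency maps derived from frame-sampled movies, linear
    interpolation of the threshold crossing leaves a sawtooth ripple with
    spatial period ``speed / (frame_rate * pitch)`` pixels; a mean filter
    at that scale (``smooth_mean_px``, e.g. 7 at 40 Hz / 0.1 mm pitch /
    ~30 mm/s) removes the ripple without biasing a linear ramp.  A border
    margin the size of the filters is marked invalid.
    """
    geom = geometry or latency_map.geometry
    t = latency_map.latency_s
    if np.isfinite(t).sum() < 9:
        raise DegenerateMapError("need at least a 3 x 3 block of valid pixels")
    ts = _nanmedian_filter(t, smooth_px)
    margin = smooth_px // 2
    if smooth_mean_px > 1:
        ts = ndimage.uniform_filter(ts, size=smooth_mean_px, mode="nearest")
        margin += smooth_mean_px // 2
    pitch = geom.pixel_pitch_mm
    H, W = ts.shape
    # central differences; rows run anterior -> posterior so d/dAP = -d/drow
    dt_drow = np.full((H, W), np.nan)
    dt_dcol = np.full((H, W), np.nan)
    dt_drow[1:-1, :] = (ts[2:, :] - ts[:-2, :]) / (2 * pitch)
    dt_dcol[:, 1:-1] = (ts[:, 2:] - ts[:, :-2]) / (2 * pitch)
    if margin > 0:
        for arr in (dt_drow, dt_dcol):
            arr[:margin, :] = np.nan
            arr[-margin:, :] = np.nan
            arr[:, :margin] = np.nan
            arr[:, -margin:] = np.nan
    g_ap = -dt_drow
    g_ml = dt_dcol
    slowness = np.hypot(g_ap, g_ml)  # s/mm
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = 1.0 / slowness
    direction = np.asarray(wrap_angle(np.arctan2(g_ml, g_ap)))
    valid = (np.isfinite(slowness) & (slowness > 1.0 / max_speed_mm_s))
    if not valid.any():
        raise DegenerateMapError("all pixels invalid (flat or empty map)")
    return VelocityField(speed_mm_s=speed, direction_rad=direction,
                         valid=valid, geometry=geom)


def mean_velocity_vector(field: VelocityField) -> Tuple[float, float]:
    """Cartesian mean of the valid per-pixel velocity vectors.

    Returns ``(speed_mm_s, direction_rad)`` of the vector average;
    opposite vectors cancel.
    """
    ang, spd = field.vectors()
    if len(ang) == 0:
        raise DegenerateFieldError("no valid pixels")
    v_ap = float(np.mean(spd * np.cos(ang)))
    v_ml = float(np.mean(spd * np.sin(ang)))
    return float(np.hypot(v_ap, v_ml)), float(wrap_angle(np.arctan2(v_ml, v_ap)))


# ----------------------------------------------------------------------
# activation distributions
# ----------------------------------------------------------------------

def activation_distribution(movie: Movie, n_bins: int = 20,
                            percentiles: Tuple[float, float] = (1.0, 99.0),
                            min_duration_s: float = 10.0) -> ActivationHistogram:
    """Histogram of the normalized field-of-view mean trace.

    The spatial mean intensity trace is min-max normalized to [0, 1]
    activation using robust (1st/99th percentile) bounds and histogrammed
    into ``n_bins`` equal bins of probability mass.  Invariant to affine
    rescaling of the raw intensities.
    """
    if movie.duration_s < min_duration_s:
        raise ValueError(f"movie must be at least {min_duration_s} s long")
    trace = np.nanmean(movie.frames.reshape(movie.n_frames, -1), axis=1)
    lo, hi = np.percentile(trace, percentiles)
    if hi - lo <= 0:
        raise DegenerateNormalizationError("constant mean trace")
    act = np.clip((trace - lo) / (hi - lo), 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(act, bins=edges)
    return ActivationHistogram(bin_edges=edges, mass=counts / counts.sum())


def compare_distributions_permutation(
    hists_a: Sequence[ActivationHistogram] | np.ndarray,
    hists_b: Sequence[ActivationHistogram] | np.ndarray,
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bin permutation test of two groups of activation histograms.

    The statistic per bin is the difference of group means of bin mass;
    the null is built by permuting animal group labels.  Two-sided p-values
    use ``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)`` (ties count), then
    Bonferroni adjustment over bins (capped at 1).

    Returns ``(p_raw, p_adjusted)`` arrays of length n_bins.
    """
    A = np.asarray([h.mass if isinstance(h, ActivationHistogram) else h
                    for h in hists_a], dtype=float)
    B = np.asarray([h.mass if isinstance(h, ActivationHistogram) else h
                    for h in hists_b], dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("histogram stacks must be 2-D with matching bins")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 animals per group")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value floor")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([A, B])
    n_a, n_tot = len(A), len(pooled)
    obs = A.mean(axis=0) - B.mean(axis=0)
    count = np.zeros(pooled.shape[1], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n_tot)
        perm = pooled[idx[:n_a]].mean(axis=0) - pooled[idx[n_a:]].mean(axis=0)
        count += np.abs(perm) >= np.abs(obs) - 1e-12
    p_raw = (1.0 + count) / (n_perm + 1.0)
    p_adj = np.minimum(p_raw * pooled.shape[1], 1.0)
    return p_raw, p_adj
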