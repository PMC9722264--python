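"""Multitaper spectral analysis of LFP-like signals.

Time-frequency power via discrete prolate spheroidal (Slepian) tapers,
band-limited log fold-change quantification of stimulus responses, and
power-threshold slow-wave onset detection with refractory labelling.

Frequency bands follow the response-quantification convention:
sub-gamma 0.5-35 Hz, gamma 35-200 Hz, total 0.5-200 Hz.  Display
spectrograms conventionally restrict to 0-40 Hz with time-bandwidth
product 4, nine tapers, and a 400-ms window advanced in 200-ms steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import ndimage, signal as sps, stats

__all__ = [
    "BANDS",
    "Spectrogram",
    "BandPowerResponse",
    "multitaper_spectrogram",
    "log_fold_change",
    "detect_sw_onsets_from_power",
    "label_refractory",
    "rank_compare",
]

#: canonical response-quantification bands (Hz)
BANDS = {
    "sub_gamma": (0.5, 35.0),
    "gamma": (35.0, 200.0),
    "total": (0.5, 200.0),
}


@dataclass
class Spectrogram:
    """Multitaper time-frequency power estimate."""

    times_s: np.ndarray         # window centres
    freqs_hz: np.ndarray
    power: np.ndarray           # (n_freqs, n_times), one-sided PSD
    window_s: float
    step_s: float
    tw: float
    k: int
    fpass: Tuple[float, float]

    def peak_frequency(self) -> float:
        """Frequency (Hz) of the global power maximum."""
        i, _ = np.unravel_index(int(np.argmax(self.power)), self.power.shape)
        return float(self.freqs_hz[i])


@dataclass
class BandPowerResponse:
    """Log fold-change of band power around stimuli."""

    band: Tuple[float, float]
    band_name: str
    log_fc: float
    fold_change: float
    n_stimuli: int
    site: str = ""
    state: str = ""


def multitaper_spectrogram(
    signal: np.ndarray,
    fs: float,
    window_s: float = 0.4,
    step_s: float = 0.2,
    tw: float = 4.0,
    k: int = 9,
    fpass: Tuple[float, float] = (0.0, 40.0),
) -> Spectrogram:
    """Sliding-window multitaper power spectrogram.

    Each window's power is the mean of ``k`` Slepian-tapered one-sided
    periodograms (time-bandwidth product ``tw``), restricted to ``fpass``.
    Taper counts above ``2*tw - 1`` are accepted with a warning (the
    conventional display parameters use tw=4 with nine tapers) but the
    extra tapers are poorly concentrated.  Power is scaled as a PSD so
    that its sum times the frequency-bin width tracks the signal variance.
    """
    x = np.asarray(signal, dtype=float)
    m = int(round(window_s * fs))
    if m < 16:
        raise ValueError("window must span at least 16 samples")
    if k < 1 or k > m:
        raise ValueError("taper count k must lie in [1, window length]")
    if k > 2 * tw + 1:
        raise ValueError("taper count k must satisfy k <= 2*tw + 1")
    if k > 2 * tw - 1:
        warnings.warn(f"k={k} exceeds 2*tw-1={int(2 * tw - 1)}; the last "
                      "tapers are poorly concentrated", stacklevel=2)
    if len(x) < m:
        raise ValueError("signal shorter than one analysis window")
    tapers = sps.windows.dpss(m, NW=tw, Kmax=k)  # (k, m), unit energy
    hop = max(int(round(step_s * fs)), 1)
    starts = np.arange(0, len(x) - m + 1, hop)
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    sel = (freqs >= fpass[0]) & (freqs <= fpass[1])
    power = np.empty((int(sel.sum()), len(starts)))
    # one-sided scaling: double all bins except DC and (for even m) Nyquist
    scale = np.full(len(freqs), 2.0 / fs)
    scale[0] = 1.0 / fs
    if m % 2 == 0:
        scale[-1] = 1.0 / fs
    for j, s0 in enumerate(starts):
        seg = x[s0:s0 + m]
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        power[:, j] = (spec.mean(axis=0) * scale)[sel]
    times = (starts + m / 2.0) / fs
    return Spectrogram(times_s=times, freqs_hz=freqs[sel], power=power,
                       window_s=window_s, step_s=step_s, tw=tw, k=k,
                       fpass=fpass)


def _bandpass(x: np.ndarray, fs: float, band: Tuple[float, float],
              order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    lo = max(band[0], 1e-3) / nyq
    hi = min(band[1], 0.99 * nyq) / nyq
    if hi <= lo:
        raise ValueError(f"band {band} incompatible with fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def _resolve_band(band: Union[str, Tuple[float, float]]) -> Tuple[Tuple[float, float], str]:
    if isinstance(band, str):
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}")
        return BANDS[band], band
    lo, hi = band
    name = next((n for n, b in BANDS.items() if b == (lo, hi)), f"{lo}-{hi}Hz")
    return (float(lo), float(hi)), name


def log_fold_change(
    signal: np.ndarray,
    fs: float,
    stimuli,
    band: Union[str, Tuple[float, float]],
    post_window: Tuple[float, float] = (0.0, 1.5),
    pre_window: Tuple[float, float] = (-0.3, -0.1),
    min_stimuli: int = 10,
    log_base: float = 10.0,
    site: str = "",
    state: str = "",
) -> BandPowerResponse:
    """Band-limited log fold-change of the stimulus-triggered average.

    The signal segments around each stimulus are averaged first, the
    average is band-limited, and the fold change is the mean power in the
    post-stimulus window (default 0-1.5 s) divided by the mean power in a
    pre-stimulus interval (default the 200 ms ending 100 ms before the
    stimulus).  Reported as ``log10`` by default.  Invariant to global
    amplitude scaling.
    """
    x = np.asarray(signal, dtype=float)
    onsets = np.asarray(getattr(stimuli, "onsets_s", stimuli), dtype=float)
    (lo, hi), name = _resolve_band(band)
    t0, t1 = min(pre_window[0], post_window[0]), max(pre_window[1], post_window[1])
    # pad the averaged segment so band-pass edge transients (significant
    # for the 0.5-Hz high-pass corner) stay outside the analysis windows
    pad_s = max(2.0 / max(lo, 0.5), 0.5)
    i_lo, i_hi = int(round((t0 - pad_s) * fs)), int(round((t1 + pad_s) * fs))
    segs = []
    for s in onsets:
        c = int(round(s * fs))
        if c + i_lo < 0 or c + i_hi > len(x):
            continue
        segs.append(x[c + i_lo:c + i_hi])
    if len(segs) < min_stimuli:
        raise ValueError(f"need >= {min_stimuli} usable stimuli, got {len(segs)}")
    avg = np.mean(segs, axis=0)
    avg_f = _bandpass(avg, fs, (lo, hi))
    t_rel = (np.arange(i_lo, i_hi)) / fs
    pre = (t_rel >= pre_window[0]) & (t_rel < pre_window[1])
    post = (t_rel >= post_window[0]) & (t_rel < post_window[1])
    p_pre = float(np.mean(avg_f[pre] ** 2))
    p_post = float(np.mean(avg_f[post] ** 2))
    if p_pre <= 0:
        raise ValueError("zero pre-stimulus power; fold change undefined")
    fc = p_post / p_pre
    return BandPowerResponse(band=(lo, hi), band_name=name,
                             log_fc=float(np.log(fc) / np.log(log_base)),
                             fold_change=fc, n_stimuli=len(segs),
                             site=site, state=state)


def detect_sw_onsets_from_power(
    signal: np.ndarray,
    fs: float,
    k_sd: float = 4.0,
    smooth_s: float = 0.1,
    merge_s: float = 0.5,
) -> np.ndarray:
    """Slow-wave onsets as 4-SD upward crossings of the power trace.

    Power over time is the squared signal smoothed over ``smooth_s``;
    onsets are upward crossings of ``mean + k_sd * SD`` of that trace,
    with crossings closer than ``merge_s`` merged.  The threshold is
    relative, so the result is invariant to amplitude scaling.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) / fs < 10.0:
        raise ValueError("recording must be at least 10 s for stable statistics")
    size = max(int(round(smooth_s * fs)), 1)
    p = ndimage.uniform_filter1d(x**2, size=size, mode="nearest")
    m, s = p.mean(), p.std()
    if s == 0:
        warnings.warn("constant signal; no onsets detectable")
        return np.empty(0)
    thresh = m + k_sd * s
    above = p > thresh
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    times = crossings / fs
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= merge_s:
            kept.append(t)
    return np.asarray(kept)


def label_refractory(stimuli, spontaneous_onsets: np.ndarray,
                     window_s: float = 2.0) -> np.ndarray:
    """True where a spontaneous onset occurred strictly within ``window_s``
    before the stimulus (the stimulus falls in the refractory period)."""
    onsets = np.asarray(getattr(stimuli, "onsets_s", stimuli), dtype=float)
    spont = np.sort(np.asarray(spontaneous_onsets, dtype=float))
    out = np.zeros(len(onsets), dtype=bool)
    for i, s in enumerate(onsets):
        j = np.searchsorted(spont, s, side="left") - 1
        out[i] = j >= 0 and (s - spont[j]) < window_s
    return out


def rank_compare(a: np.ndarray, b: np.ndarray, paired: bool = False
                 ) -> Tuple[float, float]:
    """Thin wrapper for the standard nonparametric two-group comparisons:
    Wilcoxon signed-rank (paired) or Mann-Whitney U (unpaired).

    Returns ``(statistic, p_value)``.
    """
    if paired:
        res = stats.wilcoxon(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
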