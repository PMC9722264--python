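"""Refractory-period estimation from stimulus success rates.

The slow-wave generating network is refractory for a couple of seconds
after each wave: stimuli arriving too soon after a spontaneous wave fail
to trigger a new one.  The estimator bins each stimulus by the time
elapsed since the previous spontaneous wave (0.5-s bins) and reports the
lower edge of the first bin in which the success rate strictly exceeds
the criterion (default >90%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RefractoryEstimate",
    "time_since_last",
    "estimate_refractory_period",
    "latency_interval_table",
]


@dataclass
class RefractoryEstimate:
    """Binned stimulus success rates and the derived refractory period."""

    bin_edges: np.ndarray        # contiguous from 0, width bin_s
    counts: np.ndarray           # stimuli per bin
    successes: np.ndarray
    rates: np.ndarray            # NaN where no stimuli
    refractory_period_s: float   # NaN if no bin passes
    criterion: float
    bin_s: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.refractory_period_s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_s": self.bin_edges[:-1],
            "bin_hi_s": self.bin_edges[1:],
            "n_stimuli": self.counts,
            "n_success": self.successes,
            "success_rate": self.rates,
        })

    def to_dict(self) -> dict:
        return {
            "refractory_period_s": (None if not self.defined
                                    else float(self.refractory_period_s)),
            "criterion": self.criterion,
            "bin_s": self.bin_s,
            "bin_edges_s": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "successes": self.successes.tolist(),
        }


def time_since_last(stimuli, spontaneous_onsets: np.ndarray) -> np.ndarray:
    """Time from the most recent prior spontaneous wave to each stimulus.

    Stimuli with no prior onset get NaN (flagged, excluded downstream).
    """
    onsets = np.asarray(getattr(stimuli, "onsets_s", stimuli), dtype=float)
    spont = np.sort(np.asarray(spontaneous_onsets, dtype=float))
    out = np.full(len(onsets), np.nan)
    idx = np.searchsorted(spont, onsets, side="left") - 1
    has_prior = idx >= 0
    out[has_prior] = onsets[has_prior] - spont[idx[has_prior]]
    return out


def estimate_refractory_period(
    intervals: np.ndarray,
    success_flags: np.ndarray,
    bin_s: float = 0.5,
    criterion: float = 0.90,
    max_interval_s: Optional[float] = None,
) -> RefractoryEstimate:
    """Refractory period from binned success rates.

    Intervals (time since last spontaneous wave) are binned from 0 in
    ``bin_s`` steps; the refractory period is the lower edge of the first
    bin whose success rate is strictly greater than ``criterion``.  Bins
    without stimuli are skipped (they never count as passing); if no bin
    passes, the estimate is NaN and ``defined`` is False.
    """
    intervals = np.asarray(intervals, dtype=float)
    success = np.asarray(success_flags, dtype=bool)
    if len(intervals) != len(success):
        raise ValueError("intervals and success_flags must align")
    ok = np.isfinite(intervals)
    intervals, success = intervals[ok], success[ok]
    if len(intervals) == 0:
        raise ValueError("no usable stimuli (all lacked a prior wave)")
    top = max_interval_s if max_interval_s is not None else intervals.max()
    n_bins = max(int(np.ceil(top / bin_s + 1e-9)), 1)
    edges = np.arange(n_bins + 1) * bin_s
    which = np.clip(np.floor(intervals / bin_s).astype(int), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    successes = np.bincount(which, weights=success.astype(float),
                            minlength=n_bins).astype(int)
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, successes / np.maximum(counts, 1), np.nan)
    passing = np.flatnonzero((counts > 0) & (rates > criterion))
    tau = float(edges[passing[0]]) if len(passing) else float("nan")
    return RefractoryEstimate(bin_edges=edges, counts=counts,
                              successes=successes, rates=rates,
                              refractory_period_s=tau, criterion=criterion,
                              bin_s=bin_s)


def latency_interval_table(
    stimuli,
    spontaneous_onsets: np.ndarray,
    evoked_latencies_ms: np.ndarray,
    refractory_s: float = 2.0,
) -> Tuple[pd.DataFrame, dict]:
    """Join per-stimulus latency with time-since-last-wave interval.

    Returns the joined table (interval_s, latency_ms, refractory flag)
    plus a summary with latency SD inside versus outside the refractory
    window — response-time variability is expected to be smaller outside.
    """
    onsets = np.asarray(getattr(stimuli, "onsets_s", stimuli), dtype=float)
    lat = np.asarray(evoked_latencies_ms, dtype=float)
    if len(lat) != len(onsets):
        raise ValueError("latency entries must align with stimuli")
    intervals = time_since_last(onsets, spontaneous_onsets)
    refr = intervals < refractory_s  # NaN compares False -> non-refractory
    df = pd.DataFrame({
        "stim_onset_s": onsets,
        "interval_s": intervals,
        "latency_ms": lat,
        "refractory": refr,
    })
    inside = df.loc[df.refractory, "latency_ms"].dropna()
    outside = df.loc[~df.refractory, "latency_ms"].dropna()
    summary = {
        "latency_sd_inside_ms": float(inside.std(ddof=1)) if len(inside) > 1 else float("nan"),
        "latency_sd_outside_ms": float(outside.std(ddof=1)) if len(outside) > 1 else float("nan"),
        "n_inside": int(len(inside)),
        "n_outside": int(len(outside)),
    }
    return df, summary
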