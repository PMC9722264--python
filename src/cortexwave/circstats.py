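"""Circular statistics for propagation directions.

Weighted polar distributions of velocity vectors (each direction weighted
by its speed) and a two-sample Kuiper test on weighted circular samples.

The Kuiper statistic ``V = max(F_A - F_B) + max(F_B - F_A)`` is computed
on weighted empirical CDFs and is rotation invariant by construction (a
rotation shifts both CDFs by the same amount on the circle, leaving
``max - min`` of their difference unchanged).  Because the classical
tabulated null distribution does not apply to speed-weighted samples,
significance is assessed by permuting sample labels of the (angle, weight)
pairs — exact under the null for any weighting.  Pixel vectors within one
animal are not independent, so an animal-level permutation unit is
available via per-vector unit labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .geometry import wrap_angle
from .widefield import VelocityField

__all__ = [
    "PolarDistribution",
    "weighted_polar_distribution",
    "kuiper_two_sample",
    "kuiper_statistic",
]


@dataclass
class PolarDistribution:
    """Weighted direction histogram over (-pi, pi]."""

    bin_edges: np.ndarray
    mass: np.ndarray
    n_vectors: int = 0

    def __post_init__(self) -> None:
        if np.any(self.mass < 0):
            raise ValueError("masses must be nonnegative")
        total = self.mass.sum()
        if total > 0 and abs(total - 1.0) > 1e-8:
            raise ValueError("masses must sum to 1")

    def mean_direction(self) -> float:
        """Mass-weighted circular mean direction (rad)."""
        centres = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        return float(np.arctan2((self.mass * np.sin(centres)).sum(),
                                (self.mass * np.cos(centres)).sum()))


def _pool_vectors(
    inputs: Union[VelocityField, Sequence[VelocityField],
                  Tuple[np.ndarray, np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(inputs, VelocityField):
        inputs = [inputs]
    if isinstance(inputs, tuple) and len(inputs) == 2 \
            and not isinstance(inputs[0], VelocityField):
        angles, weights = inputs
        return (np.asarray(angles, dtype=float),
                np.asarray(weights, dtype=float))
    angles, weights = [], []
    for f in inputs:
        a, w = f.vectors()
        angles.append(a)
        weights.append(w)
    return np.concatenate(angles), np.concatenate(weights)


def weighted_polar_distribution(
    velocity_fields,
    n_bins: int = 36,
) -> PolarDistribution:
    """Pool velocity vectors (across animals) into a weighted direction
    histogram, each vector contributing its speed as weight.

    Accepts a VelocityField, a sequence of them, or an
    ``(angles, weights)`` pair.
    """
    angles, weights = _pool_vectors(velocity_fields)
    if len(angles) == 0:
        raise ValueError("no valid vectors")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    mass, _ = np.histogram(np.asarray(wrap_angle(angles)), bins=edges,
                           weights=weights)
    return PolarDistribution(bin_edges=edges, mass=mass / total,
                             n_vectors=len(angles))


# ----------------------------------------------------------------------
# Kuiper two-sample test
# ----------------------------------------------------------------------

def kuiper_statistic(angles_a: np.ndarray, angles_b: np.ndarray,
                     weights_a: Optional[np.ndarray] = None,
                     weights_b: Optional[np.ndarray] = None) -> float:
    """Weighted two-sample Kuiper statistic V.

    ``V = max(F_A - F_B) + max(F_B - F_A)`` over the pooled sample points
    of the weighted empirical CDFs (the flat stretch before the first
    point, where both CDFs are 0, is included).  With equal weights this
    reduces to the classical unweighted statistic.
    """
    a = np.asarray(wrap_angle(np.asarray(angles_a, dtype=float)))
    b = np.asarray(wrap_angle(np.asarray(angles_b, dtype=float)))
    wa = np.ones(len(a)) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(len(b)) if weights_b is None else np.asarray(weights_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if wa.sum() <= 0 or wb.sum() <= 0:
        raise ValueError("each sample needs positive total weight")
    xs = np.unique(np.concatenate([a, b]))
    fa = np.zeros(len(xs))
    fb = np.zeros(len(xs))
    order_a = np.argsort(a, kind="stable")
    order_b = np.argsort(b, kind="stable")
    ca = np.concatenate([[0.0], np.cumsum(wa[order_a])]) / wa.sum()
    cb = np.concatenate([[0.0], np.cumsum(wb[order_b])]) / wb.sum()
    fa = ca[np.searchsorted(a[order_a], xs, side="right")]
    fb = cb[np.searchsorted(b[order_b], xs, side="right")]
    delta = np.concatenate([[0.0], fa - fb])
    return float(delta.max() - delta.min())


def kuiper_two_sample(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    weights_a: Optional[np.ndarray] = None,
    weights_b: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    units_a: Optional[np.ndarray] = None,
    units_b: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Two-sample Kuiper test with permutation-based significance.

    The p-value permutes sample labels of the pooled (angle, weight)
    pairs; with ``units_a``/``units_b`` given (integer label per vector,
    e.g. the animal), whole units are swapped between groups instead,
    respecting within-animal dependence.  ``p = (1 + #{V_perm >= V_obs})
    / (n_perm + 1)``.

    Returns ``(V, p_value)``.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    wa = np.ones(len(a)) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(len(b)) if weights_b is None else np.asarray(weights_b, float)
    v_obs = kuiper_statistic(a, b, wa, wb)
    rng = np.random.default_rng(seed)

    if units_a is not None or units_b is not None:
        if units_a is None or units_b is None:
            raise ValueError("give unit labels for both samples or neither")
        ua = np.asarray(units_a)
        ub = np.asarray(units_b)
        groups = ([a[ua == u] for u in np.unique(ua)]
                  + [b[ub == u] for u in np.unique(ub)])
        gweights = ([wa[ua == u] for u in np.unique(ua)]
                    + [wb[ub == u] for u in np.unique(ub)])
        n_a_units = len(np.unique(ua))
        n_units = len(groups)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n_units)
            pa = np.concatenate([groups[i] for i in idx[:n_a_units]])
            pwa = np.concatenate([gweights[i] for i in idx[:n_a_units]])
            pb = np.concatenate([groups[i] for i in idx[n_a_units:]])
            pwb = np.concatenate([gweights[i] for i in idx[n_a_units:]])
            if kuiper_statistic(pa, pb, pwa, pwb) >= v_obs - 1e-12:
                count += 1
        return v_obs, (1.0 + count) / (n_perm + 1.0)

    pooled = np.concatenate([a, b])
    pw = np.concatenate([wa, wb])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        v = kuiper_statistic(pooled[idx[:n_a]], pooled[idx[n_a:]],
                             pw[idx[:n_a]], pw[idx[n_a:]])
        if v >= v_obs - 1e-12:
            count += 1
    return v_obs, (1.0 + count) / (n_perm + 1.0)
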