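"""Activation-pattern metrics: peak recruitment, center of activity, DTW.

Three complementary summaries of a module's activation pattern over the
gait cycle:

* **peak activation** — the maximum of the pattern, indexing recruitment
  intensity;
* **center of activity (CoA)** — the circular mean phase of the pattern,
  indexing recruitment timing.  The gait cycle is mapped onto the circle,
  grid point t -> theta_t, and the resultant vector
  A = sum(cos(theta_t) * c_t), B = sum(sin(theta_t) * c_t) gives
  CoA = atan2(B, A), wrapped to [0, 2*pi).  Reported primarily as a cycle
  fraction CoA / (2*pi), with radians alongside;
* **dynamic time warping (DTW) distance** — the minimum cumulative
  |a_i - b_j| over monotone, boundary-anchored alignments of two patterns,
  insensitive to pure timing shifts but sensitive to shape and amplitude,
  making it a natural complement to CoA.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class CenterOfActivity(NamedTuple):
    """Circular mean phase of an activation pattern."""

    fraction: float  # CoA as a gait-cycle fraction in [0, 1)
    radians: float   # CoA in [0, 2*pi)


def peak_activation(c: np.ndarray) -> float:
    """Maximum of a nonnegative activation time series."""
    c = np.asarray(c, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("empty activation series")
    if np.any(c < 0):
        raise ValueError("activation series must be nonnegative")
    return float(c.max())


def center_of_activity(
    c: np.ndarray,
    duplicate_endpoint: bool = True,
    resultant_rel_tol: float | None = None,
) -> CenterOfActivity:
    """Circular center of activity of a nonnegative gait-cycle pattern.

    With ``duplicate_endpoint=True`` (the 101-point gait-grid convention,
    where the last sample repeats heel strike) grid point k of 0..T-1 maps
    to phase theta_k = 2*pi*k/(T-1); with ``False`` the T points tile the
    circle uniformly, theta_k = 2*pi*k/T, and circular-shift equivariance
    is exact.

    The CoA is undefined for an all-zero pattern and for patterns whose
    resultant vector is (numerically) zero, e.g. uniform activation; the
    default tolerance 2/T on the relative resultant length absorbs the
    spurious resultant that the duplicated endpoint induces on a uniform
    pattern.
    """
    c = np.asarray(c, dtype=float).ravel()
    T = c.size
    if T < 2:
        raise ValueError(f"need at least 2 grid points, got {T}")
    if np.any(c < 0):
        raise ValueError("activation series must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("CoA undefined: activation series is all zero")
    denom = (T - 1) if duplicate_endpoint else T
    theta = 2.0 * np.pi * np.arange(T) / denom
    A = float(np.cos(theta) @ c)
    B = float(np.sin(theta) @ c)
    if resultant_rel_tol is None:
        resultant_rel_tol = 2.0 / T
    if np.hypot(A, B) <= resultant_rel_tol * total:
        raise ValueError(
            "CoA undefined: resultant vector is (numerically) zero "
            "(near-uniform activation)"
        )
    rad = float(np.arctan2(B, A)) % (2.0 * np.pi)
    return CenterOfActivity(fraction=rad / (2.0 * np.pi), radians=rad)


def dtw_distance(c_a: np.ndarray, c_b: np.ndarray) -> float:
    """Classic dynamic-time-warping distance between two scalar series.

    Dynamic program with local cost |a_i - b_j|, symmetric step set
    {(1,0), (0,1), (1,1)}, anchored at both boundaries; returns the
    unnormalized total path cost.  Zero iff the series are identical.
    """
    a = np.asarray(c_a, dtype=float).ravel()
    b = np.asarray(c_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty time series")
    # cost[i, j] = |a_i - b_j|
    cost = np.abs(a[:, None] - b[None, :])
    D = np.empty_like(cost)
    D[0, 0] = cost[0, 0]
    D[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    D[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    for i in range(1, a.size):
        row = D[i]
        prev = D[i - 1]
        for j in range(1, b.size):
            row[j] = cost[i, j] + min(prev[j - 1], prev[j], row[j - 1])
    return float(D[-1, -1])


__all__ = ["CenterOfActivity", "peak_activation", "center_of_activity", "dtw_distance"]
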