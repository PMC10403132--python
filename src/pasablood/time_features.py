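"""Time-domain features: amplitudes, rise/fall slopes and waveform area.

The amplitude features are defined relative to a change-point partition of
the trace: the top-k (default 10) abrupt changes in segment mean split the
trace into windows; the window holding the global maximum is flanked by
part A (left) and part B (right), whose pooled mean intensity is the
baseline.  Slopes are straight-line fits over the rising flank (end of
part A to the maximum) and the falling flank (maximum to the start of
part B), with the textbook closed-form intercept/slope expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "WindowPartition",
    "SlopeFit",
    "detect_change_points",
    "partition_windows",
    "amplitude_features",
    "slope_features",
    "time_domain_area",
    "TIME_FEATURE_NAMES",
]

TIME_FEATURE_NAMES = (
    "p2p_amplitude",
    "pos_peak_amplitude",
    "neg_peak_amplitude",
    "positive_slope",
    "negative_slope",
    "time_area",
)


@njit(cache=True)
def _dp_changepoints(y, k):  # pragma: no cover - exercised via detect_change_points
    """Optimal piecewise-constant-mean partitions for 0..k change points.

    Returns (sse, back): sse[m] is the minimal total within-segment SSE with
    exactly m change points; back[m-1, j] is the argmin split position for
    the last segment of the optimal (m-segment-boundary) partition of [0, j).
    """
    n = y.shape[0]
    s1 = np.empty(n + 1)
    s2 = np.empty(n + 1)
    s1[0] = 0.0
    s2[0] = 0.0
    for i in range(n):
        s1[i + 1] = s1[i] + y[i]
        s2[i + 1] = s2[i] + y[i] * y[i]

    dp = np.empty(n + 1)
    dp[0] = np.inf
    for j in range(1, n + 1):
        s = s1[j]
        dp[j] = s2[j] - s * s / j
        if dp[j] < 0.0:
            dp[j] = 0.0

    back = np.zeros((k, n + 1), dtype=np.int64)
    sse = np.empty(k + 1)
    sse[0] = dp[n]
    nxt = np.empty(n + 1)
    for m in range(1, k + 1):
        for j in range(n + 1):
            best = np.inf
            arg = 0
            for i in range(1, j):
                prev = dp[i]
                if prev == np.inf:
                    continue
                length = j - i
                s = s1[j] - s1[i]
                cost = (s2[j] - s2[i]) - s * s / length
                if cost < 0.0:
                    cost = 0.0
                v = prev + cost
                if v < best:
                    best = v
                    arg = i
            nxt[j] = best
            back[m - 1, j] = arg
        dp[:] = nxt
        sse[m] = dp[n]
    return sse, back


def detect_change_points(
    signal, k: int = 10, min_rel_improvement: float = 1e-12
) -> np.ndarray:
    """Exact top-k change points in segment mean, by dynamic programming.

    For each m <= k the globally SSE-optimal placement of m change points is
    found (piecewise-constant mean model, squared-error cost).  Splits are
    accepted while each additional one reduces total SSE by at least
    ``min_rel_improvement`` relative to the zero-split SSE, so a constant
    signal yields no change points.  Returned indices mark the first sample
    of each new segment, sorted ascending; the result is deterministic.
    """
    y = np.ascontiguousarray(signal, dtype=float)
    n = len(y)
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the signal length {n}")
    if k == 0:
        return np.empty(0, dtype=int)

    sse, back = _dp_changepoints(y, k)
    total = sse[0]
    if total <= 0.0:
        return np.empty(0, dtype=int)
    m_star = 0
    for m in range(1, k + 1):
        if sse[m - 1] - sse[m] >= min_rel_improvement * total:
            m_star = m
        else:
            break

    cps = []
    j = n
    for m in range(m_star, 0, -1):
        j = int(back[m - 1][j])
        cps.append(j)
    return np.array(sorted(cps), dtype=int)


@dataclass(frozen=True)
class WindowPartition:
    """Change-point windows with part A / max-window / part B roles."""

    changepoints: tuple
    segments: tuple  # half-open (start, stop) index intervals
    max_segment: tuple
    part_a: tuple
    part_b: tuple
    baseline_mean: float


def partition_windows(signal, changepoints) -> WindowPartition:
    """Split the trace at the change points and locate the flanking windows.

    Part A is the window immediately left of the one containing the global
    maximum, part B the one immediately right; the baseline is the unweighted
    mean of all samples pooled over part A and part B.
    """
    y = np.asarray(signal, dtype=float)
    n = len(y)
    cps = [int(c) for c in changepoints]
    if cps != sorted(cps) or len(set(cps)) != len(cps):
        raise ValueError("changepoints must be strictly increasing")
    if cps and (cps[0] <= 0 or cps[-1] >= n):
        raise ValueError("changepoints must lie strictly inside the signal")
    bounds = [0, *cps, n]
    segments = tuple((bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    imax = int(np.argmax(y))
    seg_idx = next(i for i, (a, b) in enumerate(segments) if a <= imax < b)
    if seg_idx == 0 or seg_idx == len(segments) - 1:
        side = "first" if seg_idx == 0 else "last"
        raise ValueError(
            f"the signal maximum (sample {imax}) lies in the {side} window; "
            "no flanking window exists to define part A and part B"
        )
    part_a = segments[seg_idx - 1]
    part_b = segments[seg_idx + 1]
    pooled = np.concatenate([y[part_a[0]:part_a[1]], y[part_b[0]:part_b[1]]])
    return WindowPartition(
        changepoints=tuple(cps),
        segments=segments,
        max_segment=segments[seg_idx],
        part_a=part_a,
        part_b=part_b,
        baseline_mean=float(pooled.mean()),
    )


def amplitude_features(signal, partition: WindowPartition):
    """Peak-to-peak, positive-peak and negative-peak amplitudes.

    p2p = max − min; positive peak = max − baseline; negative peak =
    baseline − min.  By construction p2p == pos + neg exactly.
    """
    y = np.asarray(signal, dtype=float)
    p2p = float(y.max() - y.min())
    pos = float(y.max() - partition.baseline_mean)
    neg = float(partition.baseline_mean - y.min())
    return p2p, pos, neg


@dataclass(frozen=True)
class SlopeFit:
    """Closed-form least-squares line y = b x + a over a sample region."""

    a: float
    b: float
    n: int
    region: tuple  # half-open (start, stop) indices into the analyzed signal


def _fit_line(x: np.ndarray, y: np.ndarray, region) -> SlopeFit:
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    if denom == 0:
        raise ValueError("degenerate x values in slope region")
    a = (sy * sxx - sx * sxy) / denom
    b = (n * sxy - sx * sy) / denom
    return SlopeFit(a=float(a), b=float(b), n=n, region=tuple(region))


def slope_features(signal, partition: WindowPartition, dt: float, t=None):
    """Rising and falling straight-line fits around the signal maximum.

    The positive slope is fitted from the end of part A to the sample of
    maximum intensity, the negative slope from the maximum to the start of
    part B.  x is time in ms, so slopes are intensity/ms.
    """
    y = np.asarray(signal, dtype=float)
    if t is None:
        t = np.arange(len(y)) * dt
    else:
        t = np.asarray(t, dtype=float)
    imax = int(np.argmax(y))
    # inclusive endpoints: first sample after part A .. max, and
    # max .. last sample before part B
    pos_lo, pos_hi = partition.part_a[1], imax
    neg_lo, neg_hi = imax, partition.part_b[0] - 1
    if pos_hi - pos_lo + 1 < 2:
        raise ValueError("positive-slope region has fewer than 2 samples")
    if neg_hi - neg_lo + 1 < 2:
        raise ValueError("negative-slope region has fewer than 2 samples")
    pos = _fit_line(t[pos_lo:pos_hi + 1], y[pos_lo:pos_hi + 1], (pos_lo, pos_hi + 1))
    neg = _fit_line(t[neg_lo:neg_hi + 1], y[neg_lo:neg_hi + 1], (neg_lo, neg_hi + 1))
    return pos, neg


def time_domain_area(signal, dt: float) -> float:
    """Trapezoidal area under the trace, in intensity·ms."""
    y = np.asarray(signal, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two samples to integrate")
    return float(np.trapezoid(y, dx=dt))
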