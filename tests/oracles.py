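"""Brute-force oracles shared across test modules."""

import itertools

import numpy as np


def prominence_oracle(p):
    """Exhaustive contour-scan prominences for every strict local maximum."""
    n = len(p)
    out = {}
    for i in range(1, n - 1):
        if not (p[i] > p[i - 1] and p[i] > p[i + 1]):
            continue
        j = i - 1
        left_min = p[i]
        while j >= 0 and p[j] <= p[i]:
            left_min = min(left_min, p[j])
            j -= 1
        right_min = p[i]
        j = i + 1
        while j < n and p[j] <= p[i]:
            right_min = min(right_min, p[j])
            j += 1
        out[i] = p[i] - max(left_min, right_min)
    return out


def segment_sse(y, splits):
    """Total within-segment SSE of a piecewise-constant-mean partition."""
    bounds = (0, *splits, len(y))
    return sum(
        float(np.sum((y[bounds[i]:bounds[i + 1]]
                      - y[bounds[i]:bounds[i + 1]].mean()) ** 2))
        for i in range(len(bounds) - 1)
    )


def exhaustive_best_splits(y, m):
    """Brute-force optimal m-split placement minimizing total SSE."""
    best, best_cost = None, np.inf
    for splits in itertools.combinations(range(1, len(y)), m):
        cost = segment_sse(y, splits)
        if cost < best_cost:
            best, best_cost = splits, cost
    return best, best_cost
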