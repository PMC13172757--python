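"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (pure-Python loops, closed forms,
exhaustive enumeration) and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_auc(pos, neg) -> float:
    """P(X > Y) + 0.5 P(X = Y) by explicit pairwise comparison."""
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_peaks(d, t, refractory_s, min_prominence_frac):
    """Local maxima (leftmost on plateaus) + greedy refractory suppression.

    Prominence of a candidate is computed the textbook way: walk left and
    right to the first sample exceeding the peak (or the trace edge), take
    the minimum on each side, and measure from the higher of the two.
    """
    d = list(map(float, d))
    n = len(d)
    cands = []
    i = 1
    while i < n - 1:
        if d[i] > d[i - 1]:
            j = i
            while j + 1 < n and d[j + 1] == d[i]:
                j += 1
            if j < n - 1 and d[j + 1] < d[i]:
                cands.append(i)
            i = j + 1
        else:
            i += 1
    rng = max(d) - min(d)
    if rng == 0:
        return []

    def prominence(p):
        left_min = d[p]
        k = p - 1
        while k >= 0 and d[k] <= d[p]:
            left_min = min(left_min, d[k])
            k -= 1
        right_min = d[p]
        k = p + 1
        while k < n and d[k] <= d[p]:
            right_min = min(right_min, d[k])
            k += 1
        return d[p] - max(left_min, right_min)

    cands = [c for c in cands if prominence(c) >= min_prominence_frac * rng]
    kept = []
    for c in sorted(cands, key=lambda i: (-d[i], i)):
        if all(abs(t[c] - t[k]) > refractory_s for k in kept):
            kept.append(c)
    return sorted(kept)


def brute_force_youden(scores, labels):
    """Exhaustive scan of midpoint thresholds for the Youden-optimal cutoff."""
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    uniq = sorted(set(scores))
    best = None
    for a, b in zip(uniq[:-1], uniq[1:]):
        c = (a + b) / 2.0
        sens = sum(s >= c for s in pos) / len(pos)
        spec = sum(s < c for s in neg) / len(neg)
        key = (sens + spec - 1.0, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    return best[1], best[2], best[3]


def bh_step_up(p_values):
    """Hand application of the Benjamini–Hochberg step-up rule."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def spearman_by_hand(x, y):
    """Pearson correlation of average ranks, written out explicitly."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def ols_slope(y):
    """Closed-form OLS slope of y on 0-based index."""
    n = len(y)
    x = list(range(n))
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sum((a - mx) ** 2 for a in x)
    return num / den


def sample_cov(values):
    """Sample (n−1) coefficient of variation, written out explicitly."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var) / mean


def random_smooth_trace(rng: np.random.Generator, n: int, fs: float = 50.0):
    """A band-limited random trace for peak-detector equivalence checks."""
    freqs = rng.uniform(0.5, 4.0, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    amps = rng.uniform(0.2, 1.0, size=4)
    t = np.arange(n) / fs
    d = sum(a * np.sin(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases))
    return t, np.asarray(d)
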