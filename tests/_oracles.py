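"""Independent straight-line oracles used by the test suite.

Each oracle applies its defining formula literally, with plain Python loops
and no neighbour-search or FFT library, so it shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def relieff_oracle(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Literal O(n²) multi-class ReliefF.

    For every sample: k nearest hits and, per other class, k nearest misses by
    Euclidean distance (ties by lowest sample index), then the per-feature
    weight update with prior-ratio-weighted miss terms, iterating all samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    m = n
    classes = sorted(set(y.tolist()))
    prior = {c: sum(1 for v in y if v == c) / n for c in classes}
    fmax = [max(X[i, f] for i in range(n)) for f in range(p)]
    fmin = [min(X[i, f] for i in range(n)) for f in range(p)]

    def diff(f, i, j):
        span = fmax[f] - fmin[f]
        if span <= 0:
            return 0.0
        return abs(X[i, f] - X[j, f]) / span

    W = [0.0] * p
    for i in range(n):
        d = {}
        for j in range(n):
            s = 0.0
            for f in range(p):
                s += (X[i, f] - X[j, f]) ** 2
            d[j] = s  # squared distance; ordering is what matters
        hits = sorted(
            (j for j in range(n) if y[j] == y[i] and j != i),
            key=lambda j: (d[j], j),
        )[:k]
        for f in range(p):
            W[f] -= sum(diff(f, i, j) for j in hits) / (m * k)
        for c in classes:
            if c == y[i]:
                continue
            misses = sorted(
                (j for j in range(n) if y[j] == c), key=lambda j: (d[j], j)
            )[:k]
            ratio = prior[c] / (1.0 - prior[y[i]])
            for f in range(p):
                W[f] += ratio * sum(diff(f, i, j) for j in misses) / (m * k)
    return np.asarray(W)


def fscore_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Literal F-score: between-class scatter over pooled within-class scatter."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = sorted(set(y.tolist()))
    F = []
    for f in range(p):
        grand = sum(X[i, f] for i in range(n)) / n
        between = 0.0
        within = 0.0
        for c in classes:
            idx = [i for i in range(n) if y[i] == c]
            mu = sum(X[i, f] for i in idx) / len(idx)
            between += len(idx) * (mu - grand) ** 2
            within += sum((X[i, f] - mu) ** 2 for i in idx)
        if within == 0.0:
            F.append(0.0 if between == 0.0 else math.inf)
        else:
            F.append(between / within)
    return np.asarray(F)


def dft_band_power_oracle(x: np.ndarray) -> float:
    """Explicit O(N²) DFT followed by the (1/N)·Σ|X(k)|² power sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    total = 0.0
    for k in range(n):
        acc = 0j
        for t in range(n):
            acc += x[t] * cmath.exp(-2j * cmath.pi * k * t / n)
        total += abs(acc) ** 2
    return total / n


def paired_t_power_oracle(delta: float, sd: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided paired t-test via the noncentral t."""
    from scipy import stats

    df = n - 1
    ncp = delta / (sd / math.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )
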