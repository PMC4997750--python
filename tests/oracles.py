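"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive re-derivations (nested loops, bisection) of quantities the
package computes with vectorized/library code; they share no code path with
the implementation they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_reference(V, chrom, autosomal, k, exclude_same_chrom=True):
    """Exhaustive-search reference selection and leave-one-out ratio stats.

    V: (n_samples, n_bins) values over usable bins; chrom: per-bin chromosome
    labels; autosomal: per-bin bool.  Returns (ref_sets, mu, sigma).
    """
    n_samples, n_bins = V.shape

    def eligible(i, j):
        if i == j or not autosomal[j]:
            return False
        if exclude_same_chrom and chrom[i] == chrom[j]:
            return False
        return True

    def topk(dist_fn, i):
        pairs = []
        for j in range(n_bins):
            if eligible(i, j):
                pairs.append((dist_fn(i, j), j))
        pairs.sort(key=lambda t: (t[0], t[1]))
        if len(pairs) < k:
            raise ValueError(f"bin {i}: not enough eligible bins")
        return [j for _, j in pairs[:k]]

    def full_dist(i, j):
        return sum((V[s, i] - V[s, j]) ** 2 for s in range(n_samples))

    ref_sets = [topk(full_dist, i) for i in range(n_bins)]

    ratios = np.empty((n_samples, n_bins))
    for s in range(n_samples):
        def loo_dist(i, j, s=s):
            return full_dist(i, j) - (V[s, i] - V[s, j]) ** 2

        for i in range(n_bins):
            ref_s = topk(loo_dist, i)
            ratios[s, i] = V[s, i] / np.mean([V[s, j] for j in ref_s])
    mu = ratios.mean(axis=0)
    sigma = ratios.std(axis=0, ddof=1)
    return ref_sets, mu, sigma


def brute_force_windowed(z, chrom, w):
    """Direct window sums: Z_i = sum(z in truncated window) / sqrt(size)."""
    half = w // 2
    out = np.empty(len(z))
    for i in range(len(z)):
        window = [
            j
            for j in range(i - half, i + half + 1)
            if 0 <= j < len(z) and chrom[j] == chrom[i]
        ]
        out[i] = sum(z[j] for j in window) / np.sqrt(len(window))
    return out


def brute_force_segments(Z, chrom, starts, ends, threshold, merge_gap):
    """Direct scan segmentation; returns (chrom, start, end, direction) tuples."""
    segments = []
    i = 0
    n = len(Z)
    while i < n:
        if abs(Z[i]) < threshold:
            i += 1
            continue
        sign = 1 if Z[i] > 0 else -1
        c = chrom[i]
        run = [i]
        j = i + 1
        gap = 0
        while j < n and chrom[j] == c:
            if abs(Z[j]) >= threshold and (Z[j] > 0) == (sign > 0):
                run.append(j)
                gap = 0
            elif abs(Z[j]) >= threshold:
                break  # opposite-sign marked bin ends the run
            else:
                gap += 1
                if gap > merge_gap:
                    break
            j += 1
        segments.append(
            (c, int(starts[run[0]]), int(ends[run[-1]]), "gain" if sign > 0 else "loss")
        )
        i = run[-1] + 1
    return segments


def clopper_pearson_bisect(x, n, level=0.95, tol=1e-10):
    """Exact binomial CI by bisection on the binomial tail probabilities.

    Lower bound: largest p with P(X >= x | p) = alpha/2; upper bound: smallest
    p with P(X <= x | p) = alpha/2.  Returned in probability units.
    """
    alpha = 1.0 - level

    def upper_tail(p):  # P(X >= x)
        return 1.0 - stats.binom.cdf(x - 1, n, p)

    def lower_tail(p):  # P(X <= x)
        return stats.binom.cdf(x, n, p)

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, increasing=True)
    upper = 1.0 if x == n else bisect(lower_tail, alpha / 2, increasing=False)
    return lower, upper
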