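"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (incremental window updates, scipy
survival functions, bounded optimisation) used by the package: entropies are
recomputed from scratch per window, binomial tails are exact pmf sums, and
the mixture fraction is a fine grid search.
"""

import math
from collections import Counter


def naive_entropy(window: str) -> float:
    n = len(window)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(window).values()
    )


def exact_binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct pmf summation."""
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * (p ** j) * ((1 - p) ** (n - j))
    return min(total, 1.0)


def _runs(keep):
    runs = []
    i = 0
    while i < len(keep):
        if keep[i]:
            j = i
            while j < len(keep) and keep[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    return runs


def _merge_intervals(intervals, gap):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def naive_low_complexity_intervals(seq, window, k_trigger, k_extend, merge_gap):
    """Segment intervals from per-window entropies computed independently."""
    if len(seq) < window:
        return []
    h = [naive_entropy(seq[i : i + window]) for i in range(len(seq) - window + 1)]
    intervals = []
    for lo, hi in _runs([x <= k_extend for x in h]):
        if min(h[lo : hi + 1]) <= k_trigger:
            intervals.append((lo, hi + window))
    return _merge_intervals(intervals, merge_gap)


def naive_residue_bias_intervals(seq, residues, window, p, p_threshold, merge_gap):
    if len(seq) < window:
        return []
    tails = []
    for i in range(len(seq) - window + 1):
        k = sum(1 for c in seq[i : i + window] if c in residues)
        tails.append(exact_binom_tail(k, window, p))
    intervals = [
        (lo, hi + window) for lo, hi in _runs([t <= p_threshold for t in tails])
    ]
    return _merge_intervals(intervals, merge_gap)


def grid_mixture_fraction(m, c, b, step=1e-3):
    """argmin over a fine grid of ||m - (f c + (1-f) b)||."""
    best_f, best_d = 0.0, float("inf")
    n = int(round(1.0 / step))
    for i in range(n + 1):
        f = i * step
        d = math.sqrt(
            sum((mi - (f * ci + (1 - f) * bi)) ** 2 for mi, ci, bi in zip(m, c, b))
        )
        if d < best_d:
            best_f, best_d = f, d
    return best_f, best_d
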