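"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (plain loops, exhaustive enumeration)
and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def roi_signal_sort(patch: np.ndarray, signal_fraction: float) -> float:
    """Sort-and-average ROI signal: mean(top ceil(f*n)) - mean(rest),
    ties broken by row-major pixel index."""
    flat = list(patch.ravel())
    n = len(flat)
    n_sig = math.ceil(signal_fraction * n)
    order = sorted(range(n), key=lambda i: (-flat[i], i))
    top = [flat[i] for i in order[:n_sig]]
    rest = [flat[i] for i in order[n_sig:]]
    return sum(top) / len(top) - sum(rest) / len(rest)


def prominences_bruteforce(y):
    """O(n^2) saddle search for every strict local maximum (plateaus report
    their leftmost sample).  Returns (indices, prominences)."""
    y = list(map(float, y))
    n = len(y)
    idx, proms = [], []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                h = y[i]
                saddles = []
                lefts = [k for k in range(i) if y[k] > h]
                if lefts:
                    saddles.append(min(y[max(lefts) + 1: i]))
                rights = [k for k in range(j + 1, n) if y[k] > h]
                if rights:
                    saddles.append(min(y[j + 1: min(rights)]))
                ref = max(saddles) if saddles else min(y)
                idx.append(i)
                proms.append(h - ref)
            i = j + 1
        else:
            i += 1
    return np.array(idx, int), np.array(proms, float)


def wilcoxon_enumeration_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = [abs(x) for x in d]
    # midranks
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over all tables with
    the observed margins (tables as or less probable than the observed)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    p = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(1.0, p)


def longest_false_run(bools, times, min_duration):
    """Enumerate all maximal False runs; return the longest with duration at
    least min_duration as (start, end) using half-open per-sample intervals,
    or None."""
    n = len(bools)
    dt_last = times[-1] - times[-2] if n > 1 else 0.0
    edges = list(times) + [times[-1] + dt_last]
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(not bools[k] for k in range(i, j + 1)) \
                    and (i == 0 or bools[i - 1]) and (j == n - 1 or bools[j + 1]):
                runs.append((edges[i], edges[j + 1]))
    best = None
    for s, e in runs:
        if e - s >= min_duration and (best is None or e - s > best[1] - best[0]):
            best = (s, e)
    return best


def bout_stats_bruteforce(sleep_intervals, span_start, span_end):
    total = sum(e - s for s, e in sleep_intervals)
    dur = span_end - span_start
    durations = [e - s for s, e in sleep_intervals]
    return {
        "sleep_fraction": total / dur,
        "bout_frequency_per_h": len(sleep_intervals) / (dur / 3600.0),
        "mean_bout_duration_s": (sum(durations) / len(durations)) if durations else float("nan"),
    }


def count_runs_at_least(values, baseline, factor):
    """Run-length enumeration of maximal runs with value >= factor * baseline."""
    above = [v >= factor * b for v, b in zip(values, baseline)]
    count = 0
    prev = False
    for a in above:
        if a and not prev:
            count += 1
        prev = a
    return count
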