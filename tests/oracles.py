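"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the affine-gap
alignment oracles search the alignment graph directly, the Wilcoxon
oracle enumerates label assignments, and the NG86 hand values are fixed
constants computed from the counting formulas.
"""

from __future__ import annotations

import functools
import math
from itertools import combinations


def brute_force_align_score(a, b, sub, gap_open, gap_extend):
    """Best global affine-gap score by full enumeration of alignment paths.

    Gap convention: a run of length L costs gap_open + (L-1) * gap_extend.
    Exponential; only for very short sequences.
    """
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "A" else gap_open), "A")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "B" else gap_open), "B")

    rec(0, 0, 0.0, "M")
    return best


def dp_align_score(a, b, sub, gap_open, gap_extend):
    """Best global affine-gap score by memoized search of the same graph
    (exhaustive over alignment states; fast enough for 1000 trials)."""

    @functools.lru_cache(maxsize=None)
    def f(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + f(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(gap_extend if last == "A" else gap_open) + f(i + 1, j, "A"))
        if j < len(b):
            best = max(best, -(gap_extend if last == "B" else gap_open) + f(i, j + 1, "B"))
        return best

    result = f(0, 0, "M")
    f.cache_clear()
    return result


def enumerate_chains(anchors, max_gap):
    """Longest monotone chain over anchor tuples (f_order, o_order) by
    explicit enumeration of every subset (for <= ~10 anchors)."""
    n = len(anchors)
    best = 0
    for mask in range(1, 1 << n):
        chain = [anchors[i] for i in range(n) if mask >> i & 1]
        chain.sort(key=lambda t: t[0])
        for sign in (1, -1):
            ok = True
            for (f1, o1), (f2, o2) in zip(chain, chain[1:]):
                if not (1 <= f2 - f1 <= max_gap and 1 <= sign * (o2 - o1) <= max_gap):
                    ok = False
                    break
            if ok:
                best = max(best, len(chain))
    return best


def exact_rank_sum_p(x, y, alternative="two-sided"):
    """Exact Wilcoxon rank-sum p by full enumeration of C(n, n_x) label
    assignments (tie-free data only)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n, k = len(pooled), len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = k * (n + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(1, n + 1), k):
        w = sum(idx)
        total += 1
        if alternative == "two-sided":
            count += abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12
        elif alternative == "greater":
            count += w >= w_obs - 1e-12
        else:
            count += w <= w_obs + 1e-12
    return count / total


def pearson_r(x, y):
    """Closed-form Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
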