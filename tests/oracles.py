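"""Independent reference implementations used to check the package.

These deliberately use naive, brute-force strategies (dense arrays,
exhaustive pair enumeration, bp-by-bp cumulative walks) so they share no
code path with the implementations they verify.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def dense_slice_reduce(pos_to_val: dict[int, float], threshold: float, merge_distance: int):
    """Slice-reduce by scanning a dense array bp-by-bp.

    Returns a list of (start, end, peak, score, peak_value) tuples.
    """
    if not pos_to_val:
        return []
    length = max(pos_to_val) + 1
    dense = np.zeros(length)
    for p, v in pos_to_val.items():
        dense[p] = v
    surviving = dense >= threshold
    surviving &= dense > 0
    clusters = []
    current: list[int] = []
    gap = 0
    for bp in range(length):
        if surviving[bp]:
            if current and gap > merge_distance:
                clusters.append(current)
                current = []
            current.append(bp)
            gap = 0
        else:
            gap += 1
    if current:
        clusters.append(current)
    out = []
    for members in clusters:
        values = [dense[p] for p in members]
        best = max(values)
        peak = members[min(i for i, v in enumerate(values) if v == best)]
        out.append((members[0], members[-1] + 1, peak, sum(values), best))
    return out


def bhattacharyya_balance(pu: float, pd: float, md: float, mu: float) -> float:
    """Sum over arms of sqrt(observed fraction * ideal fraction)."""
    total = pu + pd + md + mu
    fractions = [pu / total, pd / total, mu / total, md / total]
    ideal = [0.0, 0.5, 0.0, 0.5]
    return sum(math.sqrt(f * q) for f, q in zip(fractions, ideal))


def kendall_tau_b(x, y) -> float:
    """Exhaustive concordant/discordant pair counting."""
    x, y = list(x), list(y)
    n = len(x)
    concordant = discordant = 0
    for i, j in combinations(range(n), 2):
        a = int(x[i] > x[j]) - int(x[i] < x[j])
        b = int(y[i] > y[j]) - int(y[i] < y[j])
        concordant += a * b > 0
        discordant += a * b < 0
    n0 = n * (n - 1) // 2

    def tie_pairs(v):
        counts = {}
        for item in v:
            counts[item] = counts.get(item, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())

    denom = math.sqrt((n0 - tie_pairs(x)) * (n0 - tie_pairs(y)))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def bh_step_up(pvalues) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def cumulative_iqr(pos_to_val: dict[int, float], lower: float, upper: float) -> int:
    """First-crossing interquantile width by an explicit cumulative walk."""
    total = sum(pos_to_val.values())
    running = 0.0
    lowpos = highpos = None
    for p in sorted(pos_to_val):
        running += pos_to_val[p]
        if lowpos is None and running / total >= lower:
            lowpos = p
        if highpos is None and running / total >= upper:
            highpos = p
            break
    return highpos - lowpos + 1


def shannon_entropy_bits(values) -> float:
    total = sum(values)
    return -sum((v / total) * math.log2(v / total) for v in values if v > 0)
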