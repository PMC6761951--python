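"""Brute-force reference implementations used only to cross-check zwdose.

Everything here is deliberately written by direct enumeration / from first
principles (hand-rolled midranks, itertools combinations, exact
hypergeometric sums) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def midranks(values) -> list[float]:
    """Tie-averaged ranks computed by explicit sorting, no library calls."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def mwu_enum(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all C(N, nx) relabelings."""
    nx = len(x)
    pooled = list(x) + list(y)
    ranks = np.asarray(midranks(pooled))
    n = len(pooled)
    u_obs = float(ranks[:nx].sum()) - nx * (nx + 1) / 2.0
    idx = np.array(list(itertools.combinations(range(n), nx)))
    u_all = ranks[idx].sum(axis=1) - nx * (nx + 1) / 2.0
    total = len(u_all)
    eps = 1e-9
    p_le = float(np.sum(u_all <= u_obs + eps)) / total
    p_ge = float(np.sum(u_all >= u_obs - eps)) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric outcomes <= observed prob."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k: int) -> float:
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = prob(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def kruskal_brute(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H from explicit midranks (H, tie factor)."""
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(t**3 - t for t in counts.values())
    denom = 1.0 - tie / (n**3 - n)
    return (h / denom if denom > 0 else 0.0), denom


def dunn_z_brute(groups, i: int, j: int) -> float:
    """Dunn z for groups i vs j from explicit pooled midranks."""
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    means = []
    start = 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(t**3 - t for t in counts.values())
    var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    se = math.sqrt(var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
    if se == 0:
        return 0.0
    return (means[i] - means[j]) / se
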