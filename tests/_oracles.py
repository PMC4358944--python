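"""Naive reference implementations used as independent oracles.

Everything here is written as plain loops over Python floats, deliberately
independent of the vectorised implementations under test.
"""

from __future__ import annotations

import math


def naive_mean_sd_threshold(values) -> tuple[float, float, float]:
    """Population mean/SD and the mean + 2 SD threshold, by explicit loops."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(var)
    return mean, sd, mean + 2.0 * sd


def naive_voxel_summary(values, threshold) -> tuple[int, float]:
    count, total = 0, 0.0
    for v in values:
        if float(v) > threshold:
            count += 1
            total += float(v)
    return count, total


def naive_pearson(green, red) -> float:
    g = [float(v) for v in green]
    r = [float(v) for v in red]
    n = len(g)
    gm = sum(g) / n
    rm = sum(r) / n
    num = sum((gi - gm) * (ri - rm) for gi, ri in zip(g, r))
    den = math.sqrt(
        sum((gi - gm) ** 2 for gi in g) * sum((ri - rm) ** 2 for ri in r)
    )
    return num / den


def naive_manders(green, red, thr_g, thr_r) -> tuple[float, float]:
    g = [float(v) for v in green]
    r = [float(v) for v in red]
    g_total = sum(gi for gi in g if gi > thr_g)
    r_total = sum(ri for ri in r if ri > thr_r)
    g_coloc = sum(gi for gi, ri in zip(g, r) if gi > thr_g and ri > thr_r)
    r_coloc = sum(ri for gi, ri in zip(g, r) if gi > thr_g and ri > thr_r)
    return g_coloc / g_total, r_coloc / r_total


def _ranks(values) -> list[float]:
    """Average ranks (1-based) with midrank ties, by sorting pairs."""
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


def naive_kruskal_h(groups) -> float:
    """Tie-corrected Kruskal-Wallis H by explicit rank computation."""
    pooled = [float(v) for g in groups for v in g]
    n_total = len(pooled)
    ranks = _ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        size = len(g)
        rbar = sum(ranks[start : start + size]) / size
        h += size * (rbar - (n_total + 1) / 2.0) ** 2
        start += size
    h *= 12.0 / (n_total * (n_total + 1))
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in counts.values())
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    return h / correction


def naive_pooled_t(a, b) -> float:
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
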