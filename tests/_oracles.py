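"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions with explicit loops and no
reliance on the library code paths it checks (scipy is used only for the
t-distribution CDF, not for any test statistic).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def ccc_brute(x, y) -> float:
    """Lin's concordance correlation from first principles (1/n moments)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2.0 * cov / (vx + vy + (mx - my) ** 2)


def _average_ranks(values) -> list[float]:
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


def spearman_brute(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx = _average_ranks(list(x))
    ry = _average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def auc_brute(a, b) -> float:
    """Orientation-free AUC by enumerating every cross-group pair (ties = 1/2)."""
    wins = 0.0
    for x in a:
        for y in b:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    frac = wins / (len(a) * len(b))
    return max(frac, 1.0 - frac)


def pooled_t_brute(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test from the closed form."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, p


def bs_brute(wildtype, mutant) -> list[float]:
    """Biological signal: all cross-group absolute differences, by double loop."""
    return [abs(x - y) for x in wildtype for y in mutant]


def ns_brute(values_i, values_j) -> list[float]:
    """Noise signal: per-lesion absolute cross-condition differences."""
    return [abs(p - q) for p, q in zip(values_i, values_j)]


def robustness_brute(wildtype, mutant, phantom_wide, alpha=0.05):
    """Whole-procedure reference: BS, per-pair NS, shared normalisation, t-tests.

    ``phantom_wide``: dict condition_id -> list of per-lesion values (aligned).
    Returns {(cond_i, cond_j): (mean_ns, t, p, robust)} for every unordered
    pair with i after j in the condition order, plus the normalised BS mean.
    """
    bs = bs_brute(wildtype, mutant)
    mu = sum(bs) / len(bs)
    sigma = math.sqrt(sum((v - mu) ** 2 for v in bs) / len(bs))
    denom = mu + sigma
    bs_n = [v / denom for v in bs]
    mean_bs = sum(bs_n) / len(bs_n)
    conditions = list(phantom_wide)
    out = {}
    for a_idx in range(len(conditions)):
        for b_idx in range(a_idx + 1, len(conditions)):
            ci, cj = conditions[b_idx], conditions[a_idx]
            ns = [v / denom for v in ns_brute(phantom_wide[ci], phantom_wide[cj])]
            t, p = pooled_t_brute(bs_n, ns)
            mean_ns = sum(ns) / len(ns)
            out[(ci, cj)] = (mean_ns, t, p, p < alpha and mean_bs > mean_ns)
    return mean_bs, out
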