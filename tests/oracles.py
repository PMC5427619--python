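"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written directly from the closed-form definition of each
statistic with plain Python loops, deliberately ignoring the vectorised
implementation under test.
"""

import math

import numpy as np


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def oracle_ttest(x1, x2):
    out = []
    for g1, g2 in zip(x1, x2):
        se = math.sqrt(_sd(g1) ** 2 / len(g1) + _sd(g2) ** 2 / len(g2))
        out.append((_mean(g1) - _mean(g2)) / se)
    return np.array(out)


def oracle_s2n(x1, x2, absolute=False):
    out = []
    for g1, g2 in zip(x1, x2):
        v = (_mean(g1) - _mean(g2)) / (_sd(g1) + _sd(g2))
        out.append(abs(v) if absolute else v)
    return np.array(out)


def oracle_difference(x1, x2):
    return np.array([_mean(g1) - _mean(g2) for g1, g2 in zip(x1, x2)])


def oracle_ratio(x1, x2, log2=False):
    out = []
    for g1, g2 in zip(x1, x2):
        r = _mean(g1) / _mean(g2)
        out.append(math.log2(r) if log2 else r)
    return np.array(out)


def oracle_msd(x1, x2, conf=0.95):
    from scipy.stats import t as tdist

    out = []
    for g1, g2 in zip(x1, x2):
        n1, n2 = len(g1), len(g2)
        sp2 = ((n1 - 1) * _sd(g1) ** 2 + (n2 - 1) * _sd(g2) ** 2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        half = tdist.ppf(0.5 + conf / 2, n1 + n2 - 2) * se
        logfc = _mean(g1) - _mean(g2)
        out.append(logfc - half if logfc > 0 else -(logfc + half))
    return np.array(out)


def oracle_wad(x1, x2, absolute=False):
    avgs = [(_mean(g1) + _mean(g2)) / 2 for g1, g2 in zip(x1, x2)]
    lo, hi = min(avgs), max(avgs)
    out = []
    for (g1, g2), a in zip(zip(x1, x2), avgs):
        w = (a - lo) / (hi - lo)
        v = (_mean(g1) - _mean(g2)) * w
        out.append(abs(v) if absolute else v)
    return np.array(out)


def oracle_fcros(x1, x2, trim=0.10):
    out = []
    for g1, g2 in zip(x1, x2):
        fcs = sorted(a - b for a in g1 for b in g2)
        k = len(fcs)
        cut = int(k * trim / 2)  # symmetric trim: total `trim`, half per tail
        kept = fcs[cut : k - cut] if k >= 3 else fcs
        out.append(_mean(kept))
    return np.array(out)


def _midranks(values):
    """Average-of-tied-positions ranks of one sequence."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def oracle_sor(x1, x2):
    out = []
    for g1, g2 in zip(x1, x2):
        ranks = _midranks(list(g1) + list(g2))
        out.append(sum(ranks[: len(g1)]))
    return np.array(out)


def oracle_bws(x1, x2):
    out = []
    for g1, g2 in zip(x1, x2):
        n1, n2 = len(g1), len(g2)
        ranks = _midranks(list(g1) + list(g2))
        r1 = sorted(ranks[:n1])
        r2 = sorted(ranks[n1:])
        b1 = 0.0
        for j in range(1, n1 + 1):
            num = (r1[j - 1] - (n2 + n1) / n1 * j) ** 2
            den = (j / (n1 + 1)) * (1 - j / (n1 + 1)) * (n2 * (n2 + n1) / n1)
            b1 += num / den
        b1 /= n1
        b2 = 0.0
        for i in range(1, n2 + 1):
            num = (r2[i - 1] - (n2 + n1) / n2 * i) ** 2
            den = (i / (n2 + 1)) * (1 - i / (n2 + 1)) * (n1 * (n2 + n1) / n2)
            b2 += num / den
        b2 /= n2
        out.append((b1 + b2) / 2)
    return np.array(out)


def oracle_mwt(x1, x2, s0_sq, d0):
    """Moderated Welch t given global hyperparameters (s0², d0)."""
    out = []
    for g1, g2 in zip(x1, x2):
        n1, n2 = len(g1), len(g2)
        v1, v2 = _sd(g1) ** 2 / n1, _sd(g2) ** 2 / n2
        sw_sq = v1 + v2
        dw = sw_sq**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        dw = max(dw, 1.0)
        if math.isinf(d0):
            se_sq = s0_sq
        else:
            se_sq = (d0 * s0_sq + dw * sw_sq) / (d0 + dw)
        out.append((_mean(g1) - _mean(g2)) / math.sqrt(se_sq))
    return np.array(out)


def oracle_relieff(values, group1_mask, k):
    """Full-pass ReliefF with range-normalised Manhattan distances."""
    n_genes, n = values.shape
    lo = values.min(axis=1)
    span = values.max(axis=1) - lo
    xn = np.zeros_like(values)
    for g in range(n_genes):
        if span[g] > 0:
            xn[g] = (values[g] - lo[g]) / span[g]
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            dist[a, b] = sum(abs(xn[g, a] - xn[g, b]) for g in range(n_genes))
    w = np.zeros(n_genes)
    for a in range(n):
        same = [(dist[a, b], b) for b in range(n) if group1_mask[b] == group1_mask[a] and b != a]
        other = [(dist[a, b], b) for b in range(n) if group1_mask[b] != group1_mask[a]]
        hits = [b for _, b in sorted(same)[:k]]
        misses = [b for _, b in sorted(other)[:k]]
        for g in range(n_genes):
            for h in hits:
                w[g] -= abs(xn[g, a] - xn[g, h]) / (n * k)
            for m in misses:
                w[g] += abs(xn[g, a] - xn[g, m]) / (n * k)
    return w


def oracle_es(sorted_abs_r, member):
    """Step-by-step running-sum walk; returns (deviations, ES)."""
    n = len(sorted_abs_r)
    n_h = sum(member)
    n_r = sum(r for r, m in zip(sorted_abs_r, member) if m)
    p_hit = p_miss = 0.0
    devs = []
    for r, m in zip(sorted_abs_r, member):
        if m:
            p_hit += r / n_r if n_r > 0 else 1.0 / n_h
        else:
            p_miss += 1.0 / (n - n_h)
        devs.append(p_hit - p_miss)
    best = max(range(n), key=lambda i: (abs(devs[i]), -i))
    return np.array(devs), devs[best]
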