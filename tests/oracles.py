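"""Independent brute-force oracles used to check the package's statistics.

These are deliberately written from the definitions with plain Python
loops and their own helper routines (ranking, trimming), sharing no code
path with the package implementation they verify.
"""

from __future__ import annotations

import math

from scipy.stats import t as t_dist


def welch_oracle(a, b):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, p-value."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, ma - mb), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def _rank_average_ties(values):
    """R-style ranks (average for ties), coded independently of scipy."""
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


def tmm_oracle(counts_rows, lib_sizes=None, logratio_trim=0.3, abundance_trim=0.05):
    """Brute-force TMM factors for a genes x samples list-of-rows matrix.

    Follows the published definition step by step: reference = sample whose
    upper quartile (of counts scaled by library size) is closest to the mean
    upper quartile; per sample, drop zero-count genes, doubly trim M and A,
    weight by inverse asymptotic variance; rescale to geometric mean 1.
    """
    n_genes = len(counts_rows)
    n_samples = len(counts_rows[0])
    cols = [[counts_rows[g][s] for g in range(n_genes)] for s in range(n_samples)]
    if lib_sizes is None:
        lib_sizes = [sum(col) for col in cols]

    def upper_quartile(col):
        xs = sorted(col)
        # linear interpolation at p=0.75 (R type-7 / numpy default)
        h = (len(xs) - 1) * 0.75
        lo = math.floor(h)
        hi = math.ceil(h)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    f75 = [upper_quartile(cols[s]) / lib_sizes[s] for s in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - mean75))

    raw = []
    for s in range(n_samples):
        ms, as_, ws = [], [], []
        for g in range(n_genes):
            o, r = cols[s][g], cols[ref][g]
            if o <= 0 or r <= 0:
                continue
            po = o / lib_sizes[s]
            pr = r / lib_sizes[ref]
            ms.append(math.log2(po / pr))
            as_.append(0.5 * math.log2(po * pr))
            ws.append(
                (lib_sizes[s] - o) / (lib_sizes[s] * o)
                + (lib_sizes[ref] - r) / (lib_sizes[ref] * r)
            )
        if not ms or max(abs(m) for m in ms) < 1e-6:
            raw.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abundance_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = _rank_average_ties(ms)
        rank_a = _rank_average_ties(as_)
        num = den = 0.0
        for k in range(n):
            if lo_m <= rank_m[k] <= hi_m and lo_a <= rank_a[k] <= hi_a:
                num += ms[k] / ws[k]  # inverse-variance weighting
                den += 1.0 / ws[k]
        raw.append(2.0 ** (num / den) if den > 0 else 1.0)
    log_mean = sum(math.log(f) for f in raw) / n_samples
    return [f / math.exp(log_mean) for f in raw]


def logcpm_oracle(count, lib_size, factor, prior=0.5):
    """Direct recomputation of one logCPM cell."""
    eff = lib_size * factor
    return math.log2((count + prior) / (eff + 2.0 * prior) * 1e6)


def rpkm_oracle(logcpm_value, length_nt):
    return 2.0**logcpm_value / (length_nt / 1000.0)


def ir_ratio_oracle(intron_depths, flank_depths):
    """Mean intron depth over mean pooled flank depth from raw base lists."""
    exon_mean = sum(flank_depths) / len(flank_depths)
    if exon_mean == 0:
        return float("nan")
    return (sum(intron_depths) / len(intron_depths)) / exon_mean


def as_ratio_oracle(supporting, non_supporting, pseudocount=1.0):
    return (supporting + pseudocount) / (non_supporting + pseudocount)


def expression_ratio_oracle(supporting, unique_reads, pseudocount=1.0):
    return (supporting + pseudocount) / (unique_reads + pseudocount)
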