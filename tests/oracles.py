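"""Independent brute-force oracles used to check the library.

Everything here is written with explicit loops and elementary formulas,
deliberately sharing no code with the package: sample SDs from the
definitional sum of squares, Spearman via Pearson on hand-assigned
average ranks, OLS via the normal equations, geNorm/NormFinder from
their published definitions.
"""

from __future__ import annotations

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def rpkm_oracle(count, length_bp, total_counts):
    return count * 1e9 / (length_bp * total_counts)


def delta_ct_oracle(cq: dict[str, list[float]]) -> dict[str, float]:
    """Mean over other genes of the SD of pairwise Cq differences."""
    genes = list(cq)
    out = {}
    for gi in genes:
        sds = []
        for gj in genes:
            if gj == gi:
                continue
            diffs = [a - b for a, b in zip(cq[gi], cq[gj])]
            sds.append(sample_sd(diffs))
        out[gi] = mean(sds)
    return out


def bestkeeper_oracle(cq: dict[str, list[float]]):
    """Per-gene SD, CV%, and Pearson r with the geometric-mean index."""
    genes = list(cq)
    n = len(cq[genes[0]])
    index = []
    for j in range(n):
        prod = 1.0
        for g in genes:
            prod *= cq[g][j]
        index.append(prod ** (1.0 / len(genes)))
    out = {}
    for g in genes:
        xs = cq[g]
        sd = sample_sd(xs)
        cv = sd / mean(xs) * 100.0
        r = pearson_oracle(xs, index)
        out[g] = (sd, cv, r)
    return out


def pearson_oracle(xs, ys):
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def normfinder_oracle(cq: dict[str, list[float]]) -> dict[str, float]:
    """Ungrouped NormFinder: df-corrected residual SD of the additive model.

    y = −Cq; residuals of y_ij = α_i + β_j; with g genes
    σ̂_i² = (g/(g−2)) (s_i² − Σ_k s_k² / (g(g−1))), truncated at zero,
    where s_i² = Σ_j r_ij²/(n−1).
    """
    genes = list(cq)
    g = len(genes)
    n = len(cq[genes[0]])
    y = {gi: [-v for v in cq[gi]] for gi in genes}
    row = {gi: mean(y[gi]) for gi in genes}
    col = [mean([y[gi][j] for gi in genes]) for j in range(n)]
    grand = mean([y[gi][j] for gi in genes for j in range(n)])
    s2 = {}
    for gi in genes:
        ss = sum((y[gi][j] - row[gi] - col[j] + grand) ** 2 for j in range(n))
        s2[gi] = ss / (n - 1)
    total = sum(s2.values())
    out = {}
    for gi in genes:
        var = (g / (g - 2)) * (s2[gi] - total / (g * (g - 1)))
        out[gi] = math.sqrt(max(var, 0.0))
    return out


def genorm_oracle(cq: dict[str, list[float]], efficiency: float = 2.0):
    """geNorm M values and stepwise exclusion order from raw Cq.

    Quantities Q = E^(Cq_min − Cq); V_jk = SD of log2(Q_j/Q_k); ties on M
    exclude the lexically last gene.  Returns (initial M, exclusion order,
    final pair).
    """
    genes = list(cq)
    n = len(cq[genes[0]])
    logq = {}
    for g in genes:
        mn = min(cq[g])
        logq[g] = [(mn - c) * math.log2(efficiency) for c in cq[g]]

    def m_values(active):
        out = {}
        for gi in active:
            vs = []
            for gj in active:
                if gj == gi:
                    continue
                ratios = [logq[gi][j] - logq[gj][j] for j in range(n)]
                vs.append(sample_sd(ratios))
            out[gi] = mean(vs)
        return out

    initial = m_values(genes)
    active = list(genes)
    exclusion = []
    while len(active) > 2:
        m = m_values(active)
        worst_val = max(m.values())
        worst = max(g for g in active if m[g] == worst_val)
        exclusion.append(worst)
        active.remove(worst)
    return initial, exclusion, tuple(sorted(active))


def average_ranks(values: list[float]) -> list[float]:
    """1 = smallest; tied values share the average of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(xs, ys):
    return pearson_oracle(average_ranks(list(xs)), average_ranks(list(ys)))


def geometric_mean(xs):
    return math.exp(sum(math.log(x) for x in xs) / len(xs))


def ols_oracle(xs, ys):
    """Slope, intercept, R² from the normal equations."""
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = sum((y - slope * x - intercept) ** 2 for x, y in zip(xs, ys))
    my = sy / n
    ss_tot = sum((y - my) ** 2 for y in ys)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def shared_counts_oracle(sets: dict[str, set]):
    names = list(sets)
    common = set(sets[names[0]])
    for nm in names[1:]:
        common &= sets[nm]
    partial, unique = {}, {}
    for nm in names:
        others = set()
        for o in names:
            if o != nm:
                others |= sets[o]
        uniq = sets[nm] - others
        unique[nm] = len(uniq)
        partial[nm] = len(sets[nm]) - len(common) - len(uniq)
    return len(common), partial, unique
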