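"""Independent brute-force oracles for the scoring statistics.

Every function here evaluates the defining formula literally (explicit
loops, no shared code with the package) so the implementations under test
can be checked against them to tight tolerances on small inputs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def rank_ascending(values) -> list[float]:
    """Average ranks, smallest value rank 1 (explicit O(n^2) evaluation)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def signed_ks_oracle(e_values, m_values) -> float:
    """Signed KS distance by brute force over every threshold."""
    e = list(map(float, e_values))
    m = list(map(float, m_values))
    best_plus = 0.0   # max F_E - F_M: evidence M is stochastically larger
    best_minus = 0.0
    for x in sorted(set(e + m)):
        f_e = sum(1 for v in e if v <= x) / len(e)
        f_m = sum(1 for v in m if v <= x) / len(m)
        best_plus = max(best_plus, f_e - f_m)
        best_minus = max(best_minus, f_m - f_e)
    if best_plus > best_minus:
        return best_plus
    if best_minus > best_plus:
        return -best_minus
    return 0.0


def ssgsea_es_oracle(expression: dict[str, float], in_set, alpha: float) -> float:
    """Literal running-sum enrichment score for a single sample.

    ``expression`` maps gene -> value; genes are walked in descending
    expression order (ties kept in dict insertion order), in-set steps are
    weighted by rank**alpha where ranks are ascending average ranks, and the
    out-of-set ECDF is unweighted.
    """
    genes = list(expression)
    ranks = dict(zip(genes, rank_ascending([expression[g] for g in genes])))
    order = sorted(genes, key=lambda g: (-expression[g], genes.index(g)))
    in_set = set(in_set)
    total_w = sum(ranks[g] ** alpha for g in order if g in in_set)
    n_out = sum(1 for g in order if g not in in_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for g in order:
        if g in in_set:
            cum_in += ranks[g] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def singscore_oracle(expression: dict[str, float], in_set) -> float:
    """Normalised mean rank mapped to [-1, 1], from first principles."""
    genes = list(expression)
    ranks = dict(zip(genes, rank_ascending([expression[g] for g in genes])))
    in_set = [g for g in genes if g in set(in_set)]
    m = sum(ranks[g] for g in in_set) / len(in_set)
    n, s = len(genes), len(in_set)
    lo = (s + 1) / 2.0
    hi = n - (s - 1) / 2.0
    return 2.0 * (m - lo) / (hi - lo) - 1.0


def gs76_oracle(frame, signature_genes, anchor: str = "CDH1") -> list[float]:
    """Direct spreadsheet-style evaluation of the CDH1-weighted sum.

    ``frame`` is samples x genes (pandas DataFrame).  Weights are Pearson
    correlations with the anchor; scores are centered to mean zero.
    """
    a = [float(v) for v in frame[anchor]]
    n = len(a)

    def pearson(x, y):
        mx = sum(x) / n
        my = sum(y) / n
        num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        den = math.sqrt(sum((xi - mx) ** 2 for xi in x)) * math.sqrt(
            sum((yi - my) ** 2 for yi in y)
        )
        return num / den

    weights = {}
    for g in signature_genes:
        weights[g] = pearson([float(v) for v in frame[g]], a)
    raw = []
    for i in range(n):
        raw.append(sum(weights[g] * float(frame[g].iloc[i]) for g in signature_genes))
    mean = sum(raw) / n
    return [r - mean for r in raw]


def fao_oracle(frame, fao_genes) -> list[float]:
    """Mean of per-gene z-scores (population sd), by direct arithmetic."""
    n = len(frame)
    z_cols = {}
    for g in fao_genes:
        col = [float(v) for v in frame[g]]
        mu = sum(col) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in col) / n)
        z_cols[g] = [(v - mu) / sd for v in col]
    return [
        sum(z_cols[g][i] for g in fao_genes) / len(fao_genes) for i in range(n)
    ]


def pearson_oracle(x, y) -> tuple[float, float]:
    """Textbook Pearson r and two-sided p from the t distribution (n-2 df)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(
        sum((b - my) ** 2 for b in y)
    )
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return r, p


def ttest_oracle(a, b) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and two-sided p, by formula."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p


def tpm_oracle(counts: dict[str, list[float]], lengths: dict[str, float]) -> dict[str, list[float]]:
    """Pre-log TPM per gene, by direct per-sample arithmetic."""
    genes = list(counts)
    n = len(next(iter(counts.values())))
    out = {g: [0.0] * n for g in genes}
    for j in range(n):
        rates = {g: counts[g][j] / lengths[g] for g in genes}
        total = sum(rates.values())
        for g in genes:
            out[g][j] = rates[g] / total * 1e6
    return out
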