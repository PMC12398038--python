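"""Independent brute-force reference implementations used only by tests.

Deliberately written in plain Python with explicit intermediate vectors,
sharing no code with the package implementations they check.
"""

from __future__ import annotations

import math


def brute_force_es(gene_ids, values, members, alpha) -> float:
    """Reference ssGSEA enrichment score with explicit P_hit/P_miss vectors.

    Midranks computed by counting; genes walked in decreasing-rank order
    with lexicographic gene-id tie-break; tied-rank blocks contribute the
    end-of-block running difference once per member gene.
    """
    n = len(gene_ids)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    order = sorted(range(n), key=lambda i: (-ranks[i], gene_ids[i]))
    in_set = [gene_ids[i] in members for i in order]
    sorted_ranks = [ranks[i] for i in order]
    n_hit = sum(in_set)
    if n_hit == 0 or n_hit == n:
        raise ValueError("degenerate set")
    denom = sum(sorted_ranks[i] ** alpha for i in range(n) if in_set[i])
    p_hit, p_miss = [], []
    h = m = 0.0
    for i in range(n):
        if in_set[i]:
            h += sorted_ranks[i] ** alpha
        else:
            m += 1.0
        p_hit.append(h / denom)
        p_miss.append(m / (n - n_hit))
    es = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_ranks[j + 1] == sorted_ranks[i]:
            j += 1
        es += (j - i + 1) * (p_hit[j] - p_miss[j])
        i = j + 1
    return es


def pairwise_auc(pos, neg) -> float:
    """AUC by exhaustive pair enumeration: wins + half-ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t, its Welch–Satterthwaite df, and two-sided p."""
    from scipy.stats import t as t_dist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def logrank_by_tabulation(time, event, group) -> float:
    """Two-group log-rank chi-square by explicit O/E/V tabulation."""
    levels = sorted(set(group))
    assert len(levels) == 2
    o = e = v = 0.0
    for t in sorted({time[i] for i in range(len(time)) if event[i] == 1}):
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group[i] == levels[0])
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        d = len(deaths)
        d1 = sum(1 for i in deaths if group[i] == levels[0])
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


def pearson_by_formula(x, y) -> tuple[float, float]:
    """Pearson r by the raw-sum formula plus its two-sided t-transform p."""
    from scipy.stats import t as t_dist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * t_dist.sf(abs(t), n - 2)
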