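"""Independent brute-force oracles used by the tests.

Deliberately naive implementations, written from the textbook definitions
and kept separate from the package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def pooled_t(a, b):
    """Classical two-sample pooled-variance t of b vs a."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted q-values via the classical step-up rule."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def bh_reject(pvals, alpha):
    """The rejection set from the step-up rule itself (not via q-values)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= rank * alpha / m:
            k_star = rank
    return set(order[:k_star])


def average_linkage_partition(dist, cut):
    """Exhaustive agglomerative average-linkage merging cut at ``cut``.

    Inter-cluster distance is the mean of the original pairwise distances.
    Returns the partition as a list of sorted index tuples.
    """
    dist = np.asarray(dist, float)
    clusters = [[i] for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best, pair = np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best:
                    best, pair = d, (i, j)
        if best > cut:
            break
        i, j = pair
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(tuple(sorted(c)) for c in clusters)


def composite_index_direct(sd, abs_pcc, members):
    """CI by direct loops: mean member SD, mean member-pair |PCC|,
    mean member x non-member |PCC|."""
    members = list(members)
    outside = [i for i in range(len(sd)) if i not in set(members)]
    sd_in = float(np.mean([sd[i] for i in members]))
    pairs = [abs_pcc[a, b] for k, a in enumerate(members) for b in members[k + 1:]]
    pcc_in = float(np.mean(pairs))
    cross = [abs_pcc[a, b] for a in members for b in outside]
    pcc_out = float(np.mean(cross))
    return sd_in * pcc_in / max(pcc_out, 1e-6), sd_in, pcc_in, pcc_out


def hypergeom_pmf(N, K, n, k):
    """Exact hypergeometric pmf from binomial coefficients."""
    if k < max(0, n - (N - K)) or k > min(K, n):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_upper(N, K, n, k):
    """P(X >= k) as a finite sum of exact pmf terms."""
    return sum(hypergeom_pmf(N, K, n, j) for j in range(k, min(K, n) + 1))


def km_product(times, events):
    """Step-by-step product-limit: {event time: S(t)} with events-first ties."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s, out = 1.0, {}
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def logrank_chi2(times, events, groups):
    """Two-group log-rank statistic from the O/E/V table, plus its p."""
    import scipy.stats as st

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    assert len(labels) == 2
    g1 = groups == labels[0]
    O = E = V = 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n_all, n1 = int(at.sum()), int((at & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        O += d1
        E += d * n1 / n_all
        if n_all > 1:
            V += d * (n1 / n_all) * (1 - n1 / n_all) * (n_all - d) / (n_all - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(st.chi2.sf(chi2, 1))


def f_oneway_direct(groups):
    """One-way ANOVA F from the sum-of-squares decomposition."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))
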