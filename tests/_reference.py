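"""Independent naive oracles used by the test suite.

Everything here is deliberately written as direct double/triple loops
(or as a separate minimal simulator), sharing no code with the package
implementation it checks.
"""

import math
import random

import numpy as np


# ---------------------------------------------------------------------------
# Naive network statistics (direct-loop transcriptions of the definitions)
# ---------------------------------------------------------------------------

def naive_stats(n, edges):
    """All scalar statistics of an (n, [(i, j, w)]) graph by brute force."""
    adj = {i: set() for i in range(n)}
    w = {}
    for i, j, ww in edges:
        i, j = int(i), int(j)
        adj[i].add(j)
        adj[j].add(i)
        w[(min(i, j), max(i, j))] = float(ww)
    k = {i: len(adj[i]) for i in range(n)}
    L = len(w)

    avg_degree = sum(k.values()) / n

    avg_weight = sum(w.values()) / L if L else math.nan

    # local clustering by triple loop; c_i = 0 for k_i < 2
    c = {}
    for i in range(n):
        if k[i] < 2:
            c[i] = 0.0
            continue
        nb = sorted(adj[i])
        links = 0
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                if nb[b] in adj[nb[a]]:
                    links += 1
        c[i] = links / (k[i] * (k[i] - 1) / 2)
    avg_clustering = sum(c.values()) / n if L else math.nan

    # link overlap
    o = {}
    for (i, j), ww in w.items():
        nij = len(adj[i] & adj[j])
        denom = (k[i] - 1) + (k[j] - 1) - nij
        o[(i, j)] = nij / denom if denom > 0 else 0.0
    avg_overlap = sum(o.values()) / L if L else math.nan

    rho_ck = naive_pearson([c[i] for i in range(n)], [k[i] for i in range(n)])
    pairs = sorted(w)
    rho_ow = naive_pearson([o[p] for p in pairs], [w[p] for p in pairs])

    return {
        "k_avg": avg_degree,
        "rho_k": naive_assortativity(n, list(w)),
        "w_avg": avg_weight,
        "C": avg_clustering,
        "O": avg_overlap,
        "rho_ck": rho_ck,
        "rho_ow": rho_ow,
        "c_local": c,
        "o_link": o,
    }


def naive_pearson(x, y):
    """Textbook Pearson r from raw sums; NaN on zero variance."""
    m = len(x)
    if m < 2:
        return math.nan
    mx = sum(x) / m
    my = sum(y) / m
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def naive_assortativity(n, links):
    """Newman's excess-degree correlation from the joint distribution e_kk'.

    rho_k = sum_{kk'} k k' (e_kk' - q_k q_k') / sigma_q^2 over excess
    degrees, with e_kk' the fraction of (directed) link ends joining
    excess degrees k and k'.
    """
    if not links:
        return math.nan
    deg = {i: 0 for i in range(n)}
    for i, j in links:
        deg[i] += 1
        deg[j] += 1
    ends = []
    for i, j in links:
        ends.append((deg[i] - 1, deg[j] - 1))
        ends.append((deg[j] - 1, deg[i] - 1))
    m = len(ends)
    e = {}
    for a, b in ends:
        e[(a, b)] = e.get((a, b), 0) + 1.0 / m
    q = {}
    for (a, b), p in e.items():
        q[a] = q.get(a, 0.0) + p
    mean_q = sum(a * p for a, p in q.items())
    var_q = sum(a * a * p for a, p in q.items()) - mean_q**2
    if var_q == 0:
        return math.nan
    # sum_kk' k k' (e_kk' - q_k q_k') = E[k k'] - (sum_k k q_k)^2
    s = sum(a * b * p for (a, b), p in e.items()) - mean_q**2
    return s / var_q


# ---------------------------------------------------------------------------
# Minimal trait-free simulator (homophily checks removed entirely)
# ---------------------------------------------------------------------------

def trait_free_average_degree(n, p_r, p_delta, w_r, p_nd, p_ld, A, w_th, w0,
                              t_max, seed):
    """<k> at t_max of the model variant with no trait/feature machinery.

    Pure-Python reimplementation: GA picks a uniform random non-neighbor
    (no geography, no traits), LA is the weight-biased two-hop walk over
    all neighbors, followed by the node-deletion, link-deletion and
    aging sweeps.  Shares no code with the package.
    """
    rnd = random.Random(seed)
    adj = [dict() for _ in range(n)]  # adj[i][j] = w

    def add(i, j, w):
        adj[i][j] = w
        adj[j][i] = w

    def drop(i, j):
        del adj[i][j]
        del adj[j][i]

    for _ in range(t_max):
        order = list(range(n))
        rnd.shuffle(order)
        for i in order:
            # GA: uniform non-neighbor
            if len(adj[i]) == 0 or rnd.random() < p_r:
                for _try in range(50):
                    j = rnd.randrange(n)
                    if j != i and j not in adj[i]:
                        add(i, j, w0)
                        break
            # LA: weighted two-hop walk
            if adj[i]:
                nbrs = list(adj[i])
                weights = [adj[i][j] for j in nbrs]
                tot = sum(weights)
                if tot > 0:
                    j = rnd.choices(nbrs, weights=weights)[0]
                    second = [(l, wl) for l, wl in adj[j].items() if l != i]
                    tot2 = sum(wl for _, wl in second)
                    if second and tot2 > 0:
                        l = rnd.choices([s for s, _ in second],
                                        weights=[wl for _, wl in second])[0]
                        if l not in adj[i]:
                            if rnd.random() < p_delta:
                                add(i, l, w0)
                        else:
                            adj[i][l] += w_r
                            adj[l][i] += w_r
                        adj[i][j] += w_r
                        adj[j][i] += w_r
                        adj[j][l] += w_r
                        adj[l][j] += w_r
        # termination sweeps: ND -> LD -> aging
        if p_nd > 0:
            for i in range(n):
                if rnd.random() < p_nd:
                    for j in list(adj[i]):
                        drop(i, j)
        if p_ld > 0:
            for i in range(n):
                for j in list(adj[i]):
                    if j > i and j in adj[i] and rnd.random() < p_ld:
                        drop(i, j)
        if A > 0:
            for i in range(n):
                for j in list(adj[i]):
                    if j > i and j in adj[i]:
                        w = adj[i][j] * (1.0 - A)
                        if w < w_th:
                            drop(i, j)
                        else:
                            adj[i][j] = w
                            adj[j][i] = w
    return sum(len(a) for a in adj) / n
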