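"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (recursive enumeration, explicit
loops, exact rational arithmetic) and shares no code with the package's
implementation paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def all_cliques(net):
    """Every clique of the graph (as frozensets), singletons included."""
    vertices = sorted(net.nodes(), key=str)
    adj = {v: set(net[v]) for v in vertices}
    out = []

    def extend(clique, candidates):
        for i, v in enumerate(candidates):
            new = clique | {v}
            out.append(frozenset(new))
            extend(new, [w for w in candidates[i + 1 :] if w in adj[v]])

    extend(set(), vertices)
    return out


def bf_vertex_clique_size(net, u):
    return max(len(c) for c in all_cliques(net) if u in c)


def bf_edge_clique_size(net, u, v):
    return max(len(c) for c in all_cliques(net) if u in c and v in c)


def bf_excluding_clique_size(net, u, v):
    sizes = [len(c) for c in all_cliques(net) if u in c and v not in c]
    return max(sizes) if sizes else 1


def bf_maximal_cliques(net, min_size=1):
    cliques = set(all_cliques(net))
    for v in net.nodes():
        cliques.add(frozenset([v]))
    maximal = {c for c in cliques if not any(c < d for d in cliques)}
    return {c for c in maximal if len(c) >= min_size}


def bf_walk_similarity(weights, beta):
    """Sum of beta^{k-1}-discounted walk strengths for walks of length 1..3.

    ``weights`` is a dict {(i, j): w} over ordered index pairs (symmetric);
    returns a dict over ordered pairs including the diagonal.
    """
    idx = sorted({i for i, _ in weights} | {j for _, j in weights})
    w = {(i, j): weights.get((i, j), 0.0) for i in idx for j in idx}
    out = {}
    for a in idx:
        for b in idx:
            total = w[(a, b)]
            for x in idx:
                total += beta * w[(a, x)] * w[(x, b)]
                for y in idx:
                    total += beta * beta * w[(a, x)] * w[(x, y)] * w[(y, b)]
            out[(a, b)] = total
    return out


def bf_neighborhood_affinity(p, b):
    inter = len(set(p) & set(b))
    return inter * inter / (len(set(p)) * len(set(b)))


def bf_f_measure(ps, bs, t):
    n_cp = 0
    for p in ps:
        if any(bf_neighborhood_affinity(p, b) >= t for b in bs):
            n_cp += 1
    n_cb = 0
    for b in bs:
        if any(bf_neighborhood_affinity(p, b) >= t for p in ps):
            n_cb += 1
    precision = n_cp / len(ps)
    recall = n_cb / len(bs)
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def bf_coverage_rate(bs, ps):
    num = 0
    den = 0
    for b in bs:
        den += len(set(b))
        num += max((len(set(b) & set(p)) for p in ps), default=0)
    return num / den


def bf_geometric_accuracy(bs, ps):
    t = [[len(set(b) & set(p)) for p in ps] for b in bs]
    sn_num = sum(max(row) for row in t)
    sn_den = sum(len(set(b)) for b in bs)
    sn = sn_num / sn_den
    ppv_num = 0
    ppv_den = 0
    for j in range(len(ps)):
        col = [t[i][j] for i in range(len(bs))]
        ppv_num += max(col)
        ppv_den += sum(col)
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv, (sn * ppv) ** 0.5


def bf_separation(bs, ps):
    t = [[len(set(b) & set(p)) for p in ps] for b in bs]
    n, m = len(bs), len(ps)
    total = 0.0
    for i in range(n):
        row_sum = sum(t[i])
        for j in range(m):
            col_sum = sum(t[k][j] for k in range(n))
            if row_sum and col_sum:
                total += (t[i][j] / row_sum) * (t[i][j] / col_sum)
    sep_co = total / n
    sep_cl = total / m
    return sep_co, sep_cl, (sep_co * sep_cl) ** 0.5


def _binom(n, k):
    if k < 0 or k > n:
        return 0
    out = 1
    for i in range(k):
        out = out * (n - i) // (i + 1)
    return out


def bf_hypergeom_upper_tail(universe, group, csize, k):
    """Exact rational P(X >= k) for the hypergeometric overlap."""
    total = _binom(universe, csize)
    acc = Fraction(0)
    for i in range(k):
        acc += Fraction(_binom(group, i) * _binom(universe - group, csize - i), total)
    return float(1 - acc)
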