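"""Independent brute-force oracles used to verify the implementation.

Everything here is written from definitions (exhaustive enumeration, direct
summation, dense grid search) and deliberately shares no code with the
package modules it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np


# -- mutual information -----------------------------------------------------


def mi_bruteforce(x, y) -> float:
    """Plug-in MI from an explicit contingency table over rank bins."""
    n = len(x)
    b = math.ceil(math.sqrt(n))

    def bins(v):
        order = sorted(range(n), key=lambda i: (v[i], i))  # stable tie-break
        lab = [0] * n
        for rank, i in enumerate(order):
            lab[i] = (rank * b) // n
        return lab

    bx, by = bins(list(x)), bins(list(y))
    joint = Counter(zip(bx, by))
    px = Counter(bx)
    py = Counter(by)
    mi = 0.0
    for (i, j), c in joint.items():
        pij = c / n
        mi += pij * math.log(pij / ((px[i] / n) * (py[j] / n)))
    return mi


# -- DPI --------------------------------------------------------------------


def dpi_bruteforce(edges, tolerance: float):
    """Exhaustive triple scan over all node combinations.

    ``edges``: iterable of (a, b, mi).  Returns the set of unordered pairs
    that survive.
    """
    mi = {}
    for a, b, v in edges:
        key = frozenset((a, b))
        mi[key] = max(mi.get(key, -np.inf), v)
    nodes = sorted({n for key in mi for n in key})
    doomed = set()
    for trio in itertools.combinations(nodes, 3):
        keys = [frozenset(p) for p in itertools.combinations(trio, 2)]
        if not all(k in mi for k in keys):
            continue
        keys.sort(key=lambda k: mi[k])
        if mi[keys[0]] < (1 - tolerance) * mi[keys[1]]:
            doomed.add(keys[0])
    return set(mi) - doomed


# -- graph metrics ----------------------------------------------------------


def betweenness_oracle(g: nx.DiGraph) -> dict:
    """Sum over (s, t) pairs of the fraction of shortest paths through v."""
    out = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        for t in g.nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in g.nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                out[v] += through / len(paths)
    return out


def closeness_oracle(g: nx.DiGraph) -> dict:
    """1 / (summed shortest-path distance to reachable nodes), 0 if none."""
    out = {}
    for v in g.nodes:
        total = 0
        for t in g.nodes:
            if t != v and nx.has_path(g, v, t):
                total += nx.shortest_path_length(g, v, t)
        out[v] = 1.0 / total if total else 0.0
    return out


def constraint_oracle(g_undirected: nx.Graph) -> dict:
    """Burt constraint by direct summation with uniform tie weights."""
    out = {}
    for i in g_undirected.nodes:
        nbrs = list(g_undirected.neighbors(i))
        if not nbrs:
            out[i] = 0.0
            continue

        def p(a, b):
            deg = g_undirected.degree(a)
            return (1.0 / deg) if g_undirected.has_edge(a, b) else 0.0

        total = 0.0
        for j in nbrs:
            indirect = sum(p(i, q) * p(q, j) for q in g_undirected.neighbors(i) if q not in (i, j))
            total += (p(i, j) + indirect) ** 2
        out[i] = total
    return out


# -- multiple testing -------------------------------------------------------


def bh_bruteforce(p):
    """q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, clipped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for i in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


# -- survival ---------------------------------------------------------------


def efron_partial_loglik(beta: float, times, events, x) -> float:
    """Efron-tie partial log-likelihood for a single covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = int(tied.sum())
        ll += beta * x[tied].sum()
        risk_sum = np.exp(beta * x[risk]).sum()
        tied_sum = np.exp(beta * x[tied]).sum()
        for ell in range(d):
            ll -= math.log(risk_sum - (ell / d) * tied_sum)
    return ll


def cox_beta_grid(times, events, x, lo=-6.0, hi=6.0) -> float:
    """Dense grid search of the Efron partial likelihood, refined twice."""
    for _ in range(3):
        grid = np.linspace(lo, hi, 2001)
        lls = [efron_partial_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        span = (hi - lo) / 20
        lo, hi = best - span, best + span
    return float(best)


def km_bruteforce(times, events):
    """Product-limit estimate: list of (event time, survival after it)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = []
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


# -- GGEA -------------------------------------------------------------------


def ggea_p_exhaustive(regulator, targets, signs, scores: dict) -> float:
    """Exact permutation p over all assignments of scores to gene labels.

    p = fraction of permutations (the identity included, mirroring the
    +1 numerator convention) with null score >= observed score.
    """
    genes = sorted(scores)
    vals = [scores[g] for g in genes]

    def score_with(mapping):
        s_reg = mapping.get(regulator, 0.0)
        gam = [
            (1.0 + sg * s_reg * mapping.get(t, 0.0)) / 2.0
            for t, sg in zip(targets, signs)
        ]
        return sum(gam) / len(gam)

    obs = score_with(dict(zip(genes, vals)))
    count = 0
    total = 0
    for perm in itertools.permutations(vals):
        total += 1
        if score_with(dict(zip(genes, perm))) >= obs - 1e-12:
            count += 1
    return count / total


# -- hypergeometric ---------------------------------------------------------


def hypergeom_upper_tail_enumeration(shared, n_a, n_b, universe) -> float:
    """P(overlap >= shared) by enumerating all draws of a B-set."""
    items = range(universe)
    a_set = set(range(n_a))
    total = 0
    hits = 0
    for b_set in itertools.combinations(items, n_b):
        total += 1
        if len(a_set & set(b_set)) >= shared:
            hits += 1
    return hits / total
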