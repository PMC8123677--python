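"""Regulon overlap analysis, shadow filtering and graph-level node metrics.

A regulon that shares most of its targets with a genuinely active regulator
can look enriched purely through that overlap (the "shadow" effect);
``shadow_filter`` removes such regulons by re-testing each member of an
overlapping pair on its exclusive targets only.

Node metrics characterise the inferred regulatory graph: in-degree (how many
regulators control a target), betweenness (shortest-path flow through a
node), closeness (inverse summed distance to reachable nodes) and Burt's
constraint (redundancy of a node's ties, computed on the undirected view
because the measure presumes mutual ties).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .inference import permutation_mi_test
from .matrix import ExpressionMatrix, RegulonSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)


def jaccard_index(a, b) -> float:
    """|A n B| / |A u B|; undefined (raises) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(a & b) / len(union)


def build_graph(rs: RegulonSet) -> nx.DiGraph:
    """Directed regulator -> target graph with a ``sign`` edge attribute."""
    g = nx.DiGraph()
    for reg in rs:
        g.add_node(reg.regulator)
        for t in reg.targets:
            g.add_edge(reg.regulator, t, sign=reg.signs.get(t, 1))
    return g


def shared_target_pairs(
    rs: RegulonSet, min_jaccard: float = 0.1
) -> tuple[pd.DataFrame, dict]:
    """Regulator pairs with target-set Jaccard >= ``min_jaccard``.

    Also returns a summary with the count and fraction of regulators that
    share at least one target with any other regulator.
    """
    regs = sorted(rs.regulons)
    sets = {r: rs[r].target_set() for r in regs}
    rows = []
    sharing = set()
    for i, a in enumerate(regs):
        for b in regs[i + 1:]:
            shared = len(sets[a] & sets[b])
            if shared:
                sharing.update((a, b))
            jac = jaccard_index(sets[a], sets[b])
            if jac >= min_jaccard:
                rows.append({"regA": a, "regB": b, "jaccard": jac, "shared": shared})
    pairs = pd.DataFrame(rows, columns=["regA", "regB", "jaccard", "shared"])
    summary = {
        "n_regulators": len(regs),
        "n_sharing": len(sharing),
        "sharing_fraction": len(sharing) / len(regs) if regs else 0.0,
    }
    return pairs, summary


def hypergeometric_overlap_p(shared: int, n_a: int, n_b: int, universe: int) -> float:
    """Upper-tail probability of >= ``shared`` common targets by chance."""
    if not 0 <= shared <= min(n_a, n_b) <= universe or max(n_a, n_b) > universe:
        raise ValueError("need 0 <= shared <= min(nA, nB) <= universe and nA, nB <= universe")
    return float(hypergeom.sf(shared - 1, universe, n_a, n_b))


def shadow_filter(
    rs: RegulonSet,
    m: ExpressionMatrix,
    overlap_alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
) -> RegulonSet:
    """Remove regulons whose signal is explained by an overlapping partner.

    For every ordered pair (A, B) with a hypergeometric overlap p below
    ``overlap_alpha``, A is re-tested by the permutation MI test on the
    targets exclusive to A (not in B), with BH correction within that set.
    A is removed when it retains no significant exclusive target while B
    retains at least one.  All pairs are evaluated on the input set before
    any removal, so the outcome is order-independent.
    """
    regs = sorted(rs.regulons)
    if len(regs) < 2:
        return RegulonSet(dict(rs.regulons))
    universe = m.n_genes
    sets = {r: rs[r].target_set() for r in regs}

    rng = np.random.default_rng(seed)
    cache: dict[tuple, bool] = {}

    def has_significant_exclusive(reg: str, excl: frozenset) -> bool:
        key = (reg, excl)
        if key not in cache:
            present = [t for t in sorted(excl) if t in m.values.index]
            if not present or reg not in m.values.index:
                cache[key] = False
            else:
                res = permutation_mi_test(
                    m.values.loc[reg].to_numpy(), m.values.loc[present], n_perm, rng
                )
                cache[key] = bool((bh_adjust(res["p"].to_numpy()) <= fdr).any())
        return cache[key]

    doomed = set()
    for a in regs:
        for b in regs:
            if a == b:
                continue
            shared = len(sets[a] & sets[b])
            if shared == 0:
                continue
            p = hypergeometric_overlap_p(shared, len(sets[a]), len(sets[b]), universe)
            if p >= overlap_alpha:
                continue
            a_ok = has_significant_exclusive(a, frozenset(sets[a] - sets[b]))
            b_ok = has_significant_exclusive(b, frozenset(sets[b] - sets[a]))
            if not a_ok and b_ok:
                doomed.add(a)
    if doomed:
        logger.info("shadow filter removed %d regulons: %s", len(doomed), sorted(doomed))
    return RegulonSet({r: rs[r] for r in regs if r not in doomed})


def _closeness(g: nx.DiGraph) -> dict:
    """Inverse summed distance to reachable nodes (directed, outgoing)."""
    out = {}
    for node in g.nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        total = sum(d for v, d in dists.items() if v != node)
        out[node] = 1.0 / total if total > 0 else 0.0
    return out


def node_metrics(g: nx.DiGraph) -> pd.DataFrame:
    """In-degree, betweenness, closeness and Burt constraint per node.

    Betweenness and closeness are computed on the directed graph
    (closeness sums distances to reachable nodes only); constraint on the
    undirected view with uniform weights.  Nodes with no undirected
    neighbours have undefined constraint and are reported as 0.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["node", "in_degree", "betweenness", "closeness", "constraint"]
        )
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = _closeness(g)
    constraint = nx.constraint(g.to_undirected())
    rows = [
        {
            "node": n,
            "in_degree": g.in_degree(n),
            "betweenness": betweenness[n],
            "closeness": closeness[n],
            "constraint": 0.0 if np.isnan(constraint[n]) else constraint[n],
        }
        for n in sorted(g.nodes)
    ]
    return pd.DataFrame(rows)


def top_indegree_targets(g: nx.DiGraph, k: int) -> pd.DataFrame:
    """Targets ranked by in-degree, descending; ties broken by gene id."""
    if k < 0:
        raise ValueError("k must be >= 0")
    targets = [(n, d) for n, d in g.in_degree() if d > 0]
    targets.sort(key=lambda x: (-x[1], x[0]))
    return pd.DataFrame(targets[:k], columns=["target", "in_degree"])
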