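"""Signed TF -> target regulon inference from an expression matrix.

Stages, in pipeline order:

1. ``filter_by_min_expression`` — drop genes never reaching an FPKM floor
   (default 1.0 in at least one sample).
2. ``rescale_zero_one`` — per-gene min-max standardisation to [0, 1];
   constant genes are dropped (the scaling is undefined for them).
3. ``infer_candidate_edges`` — mutual information between each regulator and
   every other gene, permutation p-values, BH correction within regulator.
4. ``apply_dpi`` — data-processing-inequality pruning: in every fully
   connected triple the weakest edge is removed as a likely indirect
   association.
5. ``sign_edges`` — edge sign from the Spearman rank correlation of the
   regulator/target profiles (robust to the monotone zero-one rescaling).
6. ``assemble_regulons`` — group surviving edges by regulator.

Mutual information uses equal-frequency discretisation into
``B = ceil(sqrt(n))`` bins per variable and the plug-in estimator
``MI = sum_ij p_ij * ln(p_ij / (p_i p_j))`` in nats; ties are broken by
stable sort order so the estimate is deterministic.
"""

from __future__ import annotations

import logging
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .matrix import EDGE_COLUMNS, EmptyMatrixError, ExpressionMatrix, RegulonSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)

_PERM_CHUNK = 64  # permutations scored per vectorised pass


def filter_by_min_expression(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum over samples reaches ``threshold`` FPKM."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = m.values.max(axis=1) >= threshold
    out = ExpressionMatrix(m.values.loc[keep], m.condition.copy())
    logger.info("expression filter: kept %d / %d genes", out.n_genes, m.n_genes)
    return out


def rescale_zero_one(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene (x - min) / (max - min); constant genes are dropped."""
    lo = m.values.min(axis=1)
    hi = m.values.max(axis=1)
    constant = hi == lo
    if constant.any():
        logger.warning(
            "dropping %d constant genes at zero-one rescaling", int(constant.sum())
        )
    kept = m.values.loc[~constant]
    scaled = kept.sub(lo[~constant], axis=0).div((hi - lo)[~constant], axis=0)
    return ExpressionMatrix(scaled, m.condition.copy())


def _rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels; ties broken by stable sort position."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def n_bins_for(n: int) -> int:
    return int(ceil(sqrt(n)))


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """Plug-in MI (nats) for joint count arrays of shape (..., B, B)."""
    n = joint.sum(axis=(-2, -1), keepdims=True).astype(float)
    pij = joint / n
    pi = pij.sum(axis=-1, keepdims=True)
    pj = pij.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = pij * np.log(pij / (pi * pj))
    return np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(-2, -1))


def estimate_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI (nats) between two equal-length vectors, n >= 4."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    b = n_bins_for(n)
    bx = _rank_bins(x, b)
    by = _rank_bins(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b).reshape(b, b)
    return float(_mi_from_joint(joint))


def _mi_profile(x_bins: np.ndarray, gene_bins: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of one binned vector against every row of a binned gene matrix."""
    n_genes, n = gene_bins.shape
    flat = (np.arange(n_genes)[:, None] * n_bins + x_bins[None, :]) * n_bins + gene_bins
    joint = np.bincount(flat.ravel(), minlength=n_genes * n_bins * n_bins)
    return _mi_from_joint(joint.reshape(n_genes, n_bins, n_bins))


def _mi_profile_many(
    x_bins_rows: np.ndarray, gene_bins: np.ndarray, n_bins: int
) -> np.ndarray:
    """MI of each of P binned x-vectors against every gene row -> (P, G)."""
    p, n = x_bins_rows.shape
    g = gene_bins.shape[0]
    idx = (
        (np.arange(p)[:, None, None] * g + np.arange(g)[None, :, None]) * n_bins
        + x_bins_rows[:, None, :]
    ) * n_bins + gene_bins[None, :, :]
    joint = np.bincount(idx.ravel(), minlength=p * g * n_bins * n_bins)
    return _mi_from_joint(joint.reshape(p, g, n_bins, n_bins))


def permutation_mi_test(
    x: np.ndarray,
    targets: pd.DataFrame,
    n_perm: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed MI and permutation p for one regulator against target rows.

    The null permutes the regulator's sample order ``n_perm`` times and
    recomputes MI against every target;
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    n = targets.shape[1]
    b = n_bins_for(n)
    x_bins = _rank_bins(np.asarray(x, dtype=float), b)
    gene_bins = np.vstack([_rank_bins(row, b) for row in targets.to_numpy()])
    obs = _mi_profile(x_bins, gene_bins, b)
    exceed = np.zeros(len(targets), dtype=np.int64)
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        perms = np.vstack([x_bins[rng.permutation(n)] for _ in range(chunk)])
        null = _mi_profile_many(perms, gene_bins, b)
        exceed += (null >= obs[None, :]).sum(axis=0)
        done += chunk
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"target": targets.index, "mi": obs, "p": p})


def infer_candidate_edges(
    m: ExpressionMatrix,
    regulators: set | list,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-tested MI edges, BH-corrected within each regulator.

    Returns the edge table restricted to q <= fdr with columns
    regulator, target, mi, p, q.  Regulators absent from the matrix are
    skipped with a warning.
    """
    if m.n_genes == 0:
        raise EmptyMatrixError("no genes left in the matrix")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)
    present = [r for r in sorted(set(regulators)) if r in m.values.index]
    absent = sorted(set(regulators) - set(present))
    if absent:
        logger.warning("%d regulators absent from matrix (e.g. %s)", len(absent), absent[:3])
    rng = np.random.default_rng(seed)
    frames = []
    for reg in present:
        others = m.values.drop(index=reg)
        if others.empty:
            continue
        res = permutation_mi_test(m.values.loc[reg].to_numpy(), others, n_perm, rng)
        res.insert(0, "regulator", reg)
        res["q"] = bh_adjust(res["p"].to_numpy())
        frames.append(res[res["q"] <= fdr])
    if not frames:
        return pd.DataFrame(columns=["regulator", "target", "mi", "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["regulator", "target"], ignore_index=True)


def apply_dpi(edges: pd.DataFrame, tolerance: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality pruning on the undirected edge view.

    For every fully connected triple, the weakest edge is marked for removal
    when its MI is below ``(1 - tolerance) * min(other two MIs)``; marks are
    collected over all triples before any removal, so the scan order cannot
    matter.  ``tolerance=1`` disables pruning.
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must lie in [0, 1]")
    if edges.empty:
        return edges.copy()
    # undirected MI per unordered pair (max if both directions present)
    mi: dict[frozenset, float] = {}
    for r, t, v in zip(edges["regulator"], edges["target"], edges["mi"]):
        key = frozenset((r, t))
        mi[key] = max(mi.get(key, -np.inf), float(v))
    adjacency: dict[str, set] = {}
    for key in mi:
        a, b = tuple(key)
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    doomed: set[frozenset] = set()
    nodes = sorted(adjacency)
    for a in nodes:
        for b in adjacency[a]:
            if b <= a:
                continue
            for c in adjacency[a] & adjacency[b]:
                if c <= b:
                    continue
                trio = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
                vals = sorted(trio, key=lambda k: mi[k])
                if mi[vals[0]] < (1 - tolerance) * mi[vals[1]]:
                    doomed.add(vals[0])
    keep = [
        frozenset((r, t)) not in doomed
        for r, t in zip(edges["regulator"], edges["target"])
    ]
    out = edges[keep].reset_index(drop=True)
    logger.info("DPI removed %d / %d edges", len(edges) - len(out), len(edges))
    return out


def sign_edges(m: ExpressionMatrix, edges: pd.DataFrame) -> pd.DataFrame:
    """Assign each edge the sign of the regulator/target Spearman correlation.

    Edges with exactly zero rank correlation carry no direction information
    and are dropped with a warning.
    """
    if edges.empty:
        out = edges.copy()
        out["sign"] = pd.Series(dtype=int)
        return out[EDGE_COLUMNS]
    signs = []
    for r, t in zip(edges["regulator"], edges["target"]):
        rho = spearmanr(m.values.loc[r], m.values.loc[t]).statistic
        signs.append(0 if (np.isnan(rho) or rho == 0) else int(np.sign(rho)))
    out = edges.copy()
    out["sign"] = signs
    n_zero = int((out["sign"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d edges with zero Spearman correlation", n_zero)
        out = out[out["sign"] != 0]
    return out[EDGE_COLUMNS].reset_index(drop=True)


def assemble_regulons(signed_edges: pd.DataFrame) -> RegulonSet:
    """Group signed edges by regulator; logs the regulon-size summary."""
    rs = RegulonSet.from_edges(signed_edges)
    logger.info("assembled regulons: %s", rs.summary())
    return rs
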