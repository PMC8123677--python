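"""Gene graph enrichment analysis: per-sample regulon consistency scoring.

A sample's differential-expression profile is turned into fuzzy
de-regulation scores s in [-1, 1]: genes passing the DEG q-gate get
``s = clip(log2fc / cap, -1, 1)``, everything else 0.  Each signed edge
contributes a consistency

    gamma = (1 + sign * s_regulator * s_target) / 2  in [0, 1]

which is 1 for a fully concordant saturated pair (e.g. regulator up and
activated target up), 0 for a fully discordant one, and 0.5 when either
gene carries no signal.  A regulon's score S is the mean gamma over its
edges; significance comes from permuting the gene -> score assignment over
all scored genes, and per-sample BH across regulons converts p-values into
active / inactive calls at the chosen FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deg import DEGProfile
from .matrix import Regulon, RegulonSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)


def deregulation_scores(profile: DEGProfile, cap: float = 3.0, fdr: float = 0.05) -> pd.Series:
    """Signed, magnitude-capped de-regulation score per tested gene."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    rec = profile.records
    s = np.clip(rec["log2fc"].to_numpy() / cap, -1.0, 1.0)
    s[rec["q"].to_numpy() > fdr] = 0.0
    return pd.Series(s, index=rec["gene"].to_numpy(), name="s")


def edge_consistency(s_reg: float, s_tgt: float, sign: int) -> float:
    """Agreement of one signed edge with the two genes' de-regulation."""
    if abs(s_reg) > 1 or abs(s_tgt) > 1:
        raise ValueError("scores must lie in [-1, 1]")
    if sign not in (-1, 1):
        raise ValueError("sign must be +/-1")
    return (1.0 + sign * s_reg * s_tgt) / 2.0


def regulon_score(reg: Regulon, scores) -> float:
    """Mean edge consistency of a regulon under a gene -> score mapping."""
    if not reg.targets:
        raise ValueError("empty regulon")
    s_reg = float(scores.get(reg.regulator, 0.0))
    gammas = [
        edge_consistency(s_reg, float(scores.get(t, 0.0)), reg.signs.get(t, 1))
        for t in reg.targets
    ]
    return float(np.mean(gammas))


def _null_scores_matrix(
    scores: pd.Series, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm independent permutations of the score values over gene labels."""
    base = scores.to_numpy()
    out = np.tile(base, (n_perm, 1))
    return rng.permuted(out, axis=1)


def _regulon_null_scores(
    reg: Regulon, gene_index: dict, perm: np.ndarray
) -> np.ndarray:
    ri = gene_index.get(reg.regulator)
    s_reg = perm[:, ri] if ri is not None else np.zeros(len(perm))
    acc = np.zeros(len(perm))
    for t in reg.targets:
        ti = gene_index.get(t)
        s_t = perm[:, ti] if ti is not None else 0.0
        acc += (1.0 + reg.signs.get(t, 1) * s_reg * s_t) / 2.0
    return acc / len(reg.targets)


def ggea_significance(
    reg: Regulon,
    scores: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Permutation p-value for one regulon's consistency score.

    The null permutes the gene -> score assignment uniformly over all
    scored genes and recomputes S; p = (1 + #{S_null >= S_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)
    s_obs = regulon_score(reg, scores)
    rng = np.random.default_rng(seed)
    perm = _null_scores_matrix(scores, n_perm, rng)
    gene_index = {g: i for i, g in enumerate(scores.index)}
    null = _regulon_null_scores(reg, gene_index, perm)
    p = (1.0 + int((null >= s_obs).sum())) / (n_perm + 1.0)
    summary = {"s_obs": s_obs, "null_mean": float(null.mean()), "null_sd": float(null.std())}
    return p, summary


def activity_matrix(
    profiles: list[DEGProfile],
    rs: RegulonSet,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    cap: float = 3.0,
    deg_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-(sample, regulon) activity table with BH across regulons per sample.

    Columns: sample, regulator, score, p, q, active.  The permutation null
    (one set of score permutations per sample) is shared across regulons
    within that sample.
    """
    regs = sorted(rs.regulons)
    if not regs or not profiles:
        return pd.DataFrame(columns=["sample", "regulator", "score", "p", "q", "active"])
    rng = np.random.default_rng(seed)
    rows = []
    for prof in profiles:
        scores = deregulation_scores(prof, cap=cap, fdr=deg_fdr)
        gene_index = {g: i for i, g in enumerate(scores.index)}
        perm = _null_scores_matrix(scores, n_perm, rng)
        ps, ss = [], []
        for r in regs:
            s_obs = regulon_score(rs[r], scores)
            null = _regulon_null_scores(rs[r], gene_index, perm)
            ps.append((1.0 + int((null >= s_obs).sum())) / (n_perm + 1.0))
            ss.append(s_obs)
        qs = bh_adjust(ps)
        for r, s_obs, p, q in zip(regs, ss, ps, qs):
            rows.append(
                {
                    "sample": prof.sample,
                    "regulator": r,
                    "score": s_obs,
                    "p": p,
                    "q": q,
                    "active": bool(q <= fdr),
                }
            )
    return pd.DataFrame(rows)


def activation_frequency(activity: pd.DataFrame) -> pd.DataFrame:
    """Per-regulon fraction of samples called active, ranked descending."""
    if activity.empty:
        return pd.DataFrame(columns=["regulator", "n_active", "n_samples", "frequency"])
    grp = activity.groupby("regulator", sort=True)["active"]
    out = pd.DataFrame(
        {"regulator": grp.sum().index, "n_active": grp.sum().to_numpy(),
         "n_samples": grp.count().to_numpy()}
    )
    out["frequency"] = out["n_active"] / out["n_samples"]
    return out.sort_values(
        ["frequency", "regulator"], ascending=[False, True], ignore_index=True
    )
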