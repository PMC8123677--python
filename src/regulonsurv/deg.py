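"""Per-sample differential expression against a pooled benign panel.

Each tumour sample is compared gene-by-gene with the benign control samples
of its cohort: expression is log2(x + pseudocount)-transformed, the benign
panel supplies a per-gene mean and sd, and each tumour value is scored with
a one-sample z statistic

    z = (v - mu_g) / (sigma_g * sqrt(1 + 1/n_benign))

whose sqrt(1 + 1/n) factor accounts for the plug-in benign mean.  Two-sided
normal p-values are BH-adjusted over all tested genes; a gene is called
``up`` (``down``) when q <= fdr and log2FC clears +/- the fold-change
threshold.  Genes constant in the benign panel cannot form a z-score and
are excluded from testing, reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import ExpressionMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class BenignReference:
    """Per-gene log2 mean/sd over the benign panel."""

    mu: pd.Series
    sigma: pd.Series
    n_benign: int
    pseudocount: float = 1.0
    flagged: list[str] = field(default_factory=list)  # sigma == 0 genes

    def __post_init__(self) -> None:
        if self.n_benign < 2:
            raise ValueError("need at least 2 benign samples")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be >= 0")


@dataclass
class DEGProfile:
    """One sample's differential-expression calls versus the benign panel."""

    sample: str
    records: pd.DataFrame  # columns: gene, log2fc, p, q, status
    excluded: list[str] = field(default_factory=list)

    @property
    def n_up(self) -> int:
        return int((self.records["status"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.records["status"] == "down").sum())

    def by_gene(self) -> pd.DataFrame:
        return self.records.set_index("gene")


def build_benign_reference(
    m: ExpressionMatrix, pseudocount: float = 1.0
) -> BenignReference:
    """Benign-panel log2 mean and sd per gene (sample sd, ddof=1)."""
    benign = m.samples_with("benign")
    if len(benign) < 2:
        raise ValueError(f"need >= 2 benign samples, found {len(benign)}")
    log2 = np.log2(m.values[benign] + pseudocount)
    mu = log2.mean(axis=1)
    sigma = log2.std(axis=1, ddof=1)
    flagged = sigma.index[sigma == 0].tolist()
    if flagged:
        logger.warning("%d genes constant in the benign panel are excluded", len(flagged))
    return BenignReference(
        mu=mu, sigma=sigma, n_benign=len(benign), pseudocount=pseudocount, flagged=flagged
    )


def per_sample_deg(
    sample_values: pd.Series,
    ref: BenignReference,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
    sample: str = "",
) -> DEGProfile:
    """Differential-expression profile of one sample against the reference."""
    genes = sample_values.index.intersection(ref.mu.index)
    if len(genes) == 0:
        raise ValueError("sample and reference share no genes")
    if len(genes) < len(sample_values) or len(genes) < len(ref.mu):
        logger.warning(
            "sample and reference gene sets differ; testing the %d shared genes",
            len(genes),
        )
    tested = [g for g in genes if g not in set(ref.flagged)]
    v = np.log2(sample_values.loc[tested] + ref.pseudocount)
    mu = ref.mu.loc[tested]
    sigma = ref.sigma.loc[tested]
    log2fc = v - mu
    z = log2fc / (sigma * np.sqrt(1.0 + 1.0 / ref.n_benign))
    p = 2.0 * norm.sf(np.abs(z))
    q = bh_adjust(p)
    status = np.where(
        (q <= fdr) & (log2fc >= lfc_threshold),
        "up",
        np.where((q <= fdr) & (log2fc <= -lfc_threshold), "down", "ns"),
    )
    records = pd.DataFrame(
        {"gene": tested, "log2fc": log2fc.to_numpy(), "p": p, "q": q, "status": status}
    )
    excluded = [g for g in genes if g in set(ref.flagged)]
    return DEGProfile(sample=sample, records=records, excluded=excluded)


def cohort_deg_profiles(
    m: ExpressionMatrix,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> list[DEGProfile]:
    """One DEG profile per tumour sample against the cohort's benign panel."""
    ref = build_benign_reference(m, pseudocount=pseudocount)
    return [
        per_sample_deg(m.values[s], ref, lfc_threshold, fdr, sample=s)
        for s in m.samples_with("tumour")
    ]


def deg_frequency_ranking(profiles: list[DEGProfile]) -> pd.DataFrame:
    """Per-gene alteration frequency across samples, ranked descending.

    Frequency counts samples where the gene is called up or down; up and
    down frequencies are also reported separately.  Ties are ordered by
    gene id.
    """
    if not profiles:
        raise ValueError("no DEG profiles supplied")
    n = len(profiles)
    counts: dict[str, np.ndarray] = {}
    for prof in profiles:
        for gene, status in zip(prof.records["gene"], prof.records["status"]):
            c = counts.setdefault(gene, np.zeros(2, dtype=int))
            if status == "up":
                c[0] += 1
            elif status == "down":
                c[1] += 1
    rows = [
        {
            "gene": g,
            "freq_up": c[0] / n,
            "freq_down": c[1] / n,
            "freq_altered": (c[0] + c[1]) / n,
        }
        for g, c in counts.items()
    ]
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["freq_altered", "gene"], ascending=[False, True], ignore_index=True
    )
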