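"""Time-to-recurrence analysis of regulon activity and comparator signatures.

The endpoint is biochemical recurrence (BCR): a post-treatment PSA rise of
>= 2 ng/mL above the nadir (the lowest PSA observed after treatment).
Cox proportional-hazards models (Efron tie handling, Wald confidence
intervals) relate recurrence-free time to per-sample regulon activity,
clinical covariates (Gleason score and tumour stage entered as ordinal
numerics) and three formula-defined comparator signature groupings:

* mean-expression score split at the 67th percentile (TMCC11-style),
* coefficient-weighted sum split at the median (HYPOXIA-28-style),
* a rank-walk per-sample enrichment score (BROMO-10-style), an
  approximation of single-sample GSEA-type scoring.

Quantile convention: linear interpolation; ties at a split threshold go to
the low/inactive group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Raised when a Cox model cannot be identified (no events, constant covariate)."""


@dataclass
class SignatureDefinition:
    """A named gene list, optional per-gene coefficients, and a split rule."""

    name: str
    genes: list[str]
    coefficients: list[float] | None = None
    split: str = "percentile-67"  # percentile-67 | median | enrichment-based

    def __post_init__(self) -> None:
        if self.coefficients is not None and len(self.coefficients) != len(self.genes):
            raise ValueError(f"{self.name}: coefficients do not align with genes")
        if self.split not in ("percentile-67", "median", "enrichment-based"):
            raise ValueError(f"unknown split rule {self.split!r}")


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs for one fitted model."""

    table: pd.DataFrame  # index: covariate; columns hr, ci_low, ci_high, p
    n: int
    n_events: int
    formula: str


@dataclass
class KMCurve:
    """Product-limit curves per group plus a logrank p across groups."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    logrank_p: float | None
    flagged: str = ""


def bcr_event(psa_series: list[tuple[float, float]]) -> tuple[int, float]:
    """Biochemical-recurrence call from a time-ordered PSA series.

    The nadir is the running minimum of past values; the event fires at the
    first time PSA >= nadir + 2.0 ng/mL.  Otherwise the subject is censored
    at the last observation.  Returns (event flag, time).
    """
    if not psa_series:
        raise ValueError("empty PSA series")
    times = [t for t, _ in psa_series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("PSA series must be time-ordered")
    nadir = psa_series[0][1]
    for t, v in psa_series[1:]:
        if v >= nadir + 2.0:
            return 1, t
        nadir = min(nadir, v)
    return 0, psa_series[-1][0]


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CI).

    ``records`` must contain the duration, event flag and covariate columns;
    categorical two-group labels should be pre-encoded as 0/1.
    """
    df = records[[time_col, event_col] + list(covariates)].dropna()
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise DegenerateFitError("no events in the data")
    for c in covariates:
        if df[c].nunique() < 2:
            raise DegenerateFitError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=time_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    formula = f"Surv({time_col}, {event_col}) ~ " + " + ".join(covariates)
    return CoxResult(table=table, n=len(df), n_events=n_events, formula=formula)


def km_logrank(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> KMCurve:
    """Kaplan-Meier product-limit curves per group with a logrank test."""
    groups = sorted(records[group_col].astype(str).unique())
    curves = {}
    for g in groups:
        sub = records[records[group_col].astype(str) == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=g)
        ev = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[g].to_numpy(),
                "at_risk": ev["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    if len(groups) < 2:
        logger.warning("single group: logrank p undefined")
        return KMCurve(curves=curves, logrank_p=None, flagged="single group; no logrank test")
    res = multivariate_logrank_test(
        records[time_col], records[group_col].astype(str), records[event_col]
    )
    return KMCurve(curves=curves, logrank_p=float(res.p_value))


# -- comparator signature scores ------------------------------------------


def _split_groups(scores: pd.Series, threshold: float) -> pd.Series:
    """High group strictly above threshold; ties go to the low group."""
    return pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, name="group"
    )


def tmcc11_like_score(m: ExpressionMatrix, sig: SignatureDefinition) -> pd.DataFrame:
    """Mean signature-gene expression per sample, split at the 67th percentile."""
    present = [g for g in sig.genes if g in m.values.index]
    if not present:
        raise ValueError(f"no gene of signature {sig.name} present in the matrix")
    scores = m.values.loc[present].mean(axis=0)
    threshold = float(np.quantile(scores.to_numpy(), 0.67))
    return pd.DataFrame({"score": scores, "group": _split_groups(scores, threshold)})


def weighted_signature_score(m: ExpressionMatrix, sig: SignatureDefinition) -> pd.DataFrame:
    """Coefficient-weighted expression sum per sample, median split."""
    if sig.coefficients is None:
        raise ValueError(f"signature {sig.name} has no coefficients")
    coef = pd.Series(sig.coefficients, index=sig.genes)
    present = [g for g in sig.genes if g in m.values.index]
    if not present:
        raise ValueError(f"no gene of signature {sig.name} present in the matrix")
    scores = m.values.loc[present].mul(coef.loc[present], axis=0).sum(axis=0)
    threshold = float(np.median(scores.to_numpy()))
    return pd.DataFrame({"score": scores, "group": _split_groups(scores, threshold)})


def rank_walk_enrichment_score(
    m: ExpressionMatrix, gene_set: list[str], tau: float = 0.25
) -> pd.Series:
    """Per-sample rank-walk enrichment of a gene set (ssGSEA-style area score).

    Genes are ranked by expression, descending (ties broken by gene id).
    A running sum gains a rank-weighted increment ``r_i**tau / sum_in`` at
    set genes (r_i is the descending rank weight, N at the top) and loses
    ``1/(N - n_set)`` elsewhere; the score is the sum of the running-sum
    values, positive when set genes concentrate at the top of the ranking.
    """
    genes = list(m.values.index)
    in_set = [g for g in gene_set if g in genes]
    n, n_set = len(genes), len(in_set)
    if n_set == 0:
        raise ValueError("no gene of the set is present in the matrix")
    if n_set >= n:
        raise ValueError("gene set covers the whole matrix; out-set step undefined")
    in_mask_by_gene = pd.Series([g in set(in_set) for g in genes], index=genes)
    scores = {}
    for s in m.samples:
        col = m.values[s]
        order = sorted(genes, key=lambda g: (-col[g], g))
        mask = in_mask_by_gene.loc[order].to_numpy()
        rank_weight = np.arange(n, 0, -1, dtype=float) ** tau
        inc = np.where(mask, rank_weight, 0.0)
        inc_sum = inc.sum()
        steps = np.where(mask, inc / inc_sum, -1.0 / (n - n_set))
        scores[s] = float(np.cumsum(steps).sum())
    return pd.Series(scores, name="score")


def enrichment_signature_groups(
    m: ExpressionMatrix, sig: SignatureDefinition, tau: float = 0.25
) -> pd.DataFrame:
    """Rank-walk score per sample, median split into high/low groups."""
    scores = rank_walk_enrichment_score(m, sig.genes, tau=tau)
    threshold = float(np.median(scores.to_numpy()))
    return pd.DataFrame({"score": scores, "group": _split_groups(scores, threshold)})


def score_signature(m: ExpressionMatrix, sig: SignatureDefinition) -> pd.DataFrame:
    """Dispatch a signature to its scoring/splitting rule."""
    if sig.split == "percentile-67":
        return tmcc11_like_score(m, sig)
    if sig.split == "median":
        return weighted_signature_score(m, sig)
    return enrichment_signature_groups(m, sig)


# -- report assembly --------------------------------------------------------


def _binary_flag(series: pd.Series, positive: str) -> pd.Series:
    return (series.astype(str) == positive).astype(int)


def survival_report(
    records: pd.DataFrame,
    activity: pd.DataFrame,
    signature_groups: dict[str, pd.Series] | None = None,
    clinical_covariates: tuple[str, ...] = ("gleason", "stage"),
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Univariate regulon ranking plus gated multivariate hazard-ratio tables.

    * ``regulon_ranking``: univariate Cox p per regulon's per-sample active
      flag, ascending (the Table-2-style layout).
    * ``univariate``: HR / CI / p for every signature grouping and clinical
      covariate (Table-3A-style).
    * ``multivariate``: for each univariately significant (p < alpha)
      signature-like variable, the model adding the clinical covariates
      (Table-3B-style).  Empty when nothing is univariately significant.
    """
    records = records.set_index("sample") if "sample" in records.columns else records
    uni_rows = []
    regulon_rows = []

    def fit_one(flag: pd.Series, name: str) -> dict | None:
        if name in records.columns:
            df = records
        else:
            df = records.join(flag.rename(name), how="inner")
        try:
            res = cox_fit(df, [name])
        except DegenerateFitError as exc:
            logger.info("univariate %s skipped: %s", name, exc)
            return None
        row = res.table.loc[name]
        return {
            "variable": name,
            "hr": row["hr"],
            "ci_low": row["ci_low"],
            "ci_high": row["ci_high"],
            "p": row["p"],
            "n": res.n,
            "n_events": res.n_events,
        }

    if len(activity):
        for reg, grp in activity.groupby("regulator"):
            flag = grp.set_index("sample")["active"].astype(int)
            row = fit_one(flag, reg)
            if row is not None:
                regulon_rows.append(row)
    regulon_ranking = (
        pd.DataFrame(regulon_rows).sort_values(["p", "variable"], ignore_index=True)
        if regulon_rows
        else pd.DataFrame(columns=["variable", "hr", "ci_low", "ci_high", "p", "n", "n_events"])
    )

    signature_groups = signature_groups or {}
    for name, groups in signature_groups.items():
        row = fit_one(_binary_flag(groups, "high"), name)
        if row is not None:
            uni_rows.append(row)
    for cov in clinical_covariates:
        if cov in records.columns:
            row = fit_one(records[cov].astype(float), cov)
            if row is not None:
                uni_rows.append(row)
    univariate = (
        pd.DataFrame(uni_rows)
        if uni_rows
        else pd.DataFrame(columns=["variable", "hr", "ci_low", "ci_high", "p", "n", "n_events"])
    )

    multi_rows = []
    nonempty = [df for df in (regulon_ranking, univariate) if len(df)]
    candidates = pd.concat(nonempty, ignore_index=True) if nonempty else univariate
    signature_like = set(signature_groups) | set(regulon_ranking.get("variable", []))
    for _, cand in candidates.iterrows():
        name = cand["variable"]
        if name not in signature_like or cand["p"] >= alpha:
            continue
        if name in signature_groups:
            flag = _binary_flag(signature_groups[name], "high").rename(name)
        else:
            grp = activity[activity["regulator"] == name]
            flag = grp.set_index("sample")["active"].astype(int).rename(name)
        covs = [c for c in clinical_covariates if c in records.columns]
        df = records.join(flag, how="inner")
        try:
            res = cox_fit(df, [name] + covs)
        except DegenerateFitError as exc:
            logger.info("multivariate %s skipped: %s", name, exc)
            continue
        for cov_name, row in res.table.iterrows():
            multi_rows.append(
                {
                    "model": name,
                    "variable": cov_name,
                    "hr": row["hr"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                }
            )
    multivariate = (
        pd.DataFrame(multi_rows)
        if multi_rows
        else pd.DataFrame(columns=["model", "variable", "hr", "ci_low", "ci_high", "p"])
    )
    return {
        "regulon_ranking": regulon_ranking,
        "univariate": univariate,
        "multivariate": multivariate,
    }
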