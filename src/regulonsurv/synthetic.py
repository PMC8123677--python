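"""Synthetic expression, cohort and survival data with planted ground truth.

Every downstream stage (network inference, per-sample differential
expression, regulon-activity scoring, survival association) is exercised
against matrices generated here, so each stage has a parameter-recovery test
without any external download.

Generative model
----------------
Expression is log2-normal: a regulator's log2 abundance is Normal(5, 1) in
the training (orthograft-like) matrix, a target's log2 abundance is
``5 + sign * beta * (regulator - 5) + Normal(0, sigma)``, and the matrix
holds ``2**log2`` (FPKM-like, strictly positive).  The baseline of 5 keeps
all values well above the FPKM >= 1 expression filter; decoy genes are
independent Normal(5, 1) background, plus an optional low-expression decoy
block below the filter for filter tests.

In cohorts, regulon activity is a mean shift: an *active* sample has each
active regulator shifted by ``+delta`` log2 units and each of its targets by
``sign * beta * delta``; ``sigma`` is the per-gene noise sd for regulators
and targets alike, so that delta is interpretable as a z-shift of
``delta / sigma`` per gene.  Survival times are exponential with hazard
``lambda0`` (inactive) or ``lambda0 * hr`` (active), administratively
censored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

BASELINE_LOG2 = 5.0
DEFAULT_DECOYS = 200
LOW_EXPRESSION_LOG2 = -2.0  # decoy block below an FPKM-1 filter


@dataclass
class PlantedNetwork:
    """Ground-truth signed regulator -> target edges.

    ``edges`` rows are (regulator, target, sign, beta) with sign in {+1, -1}
    and effect size beta >= 0.
    """

    edges: list[tuple[str, str, int, float]]
    regulator_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        pairs = [(r, t) for r, t, _, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (regulator, target) pairs")
        regs = set(self.regulator_ids)
        for r, t, s, b in self.edges:
            if r not in regs:
                raise ValueError(f"edge regulator {r} not in regulator_ids")
            if s not in (-1, 1):
                raise ValueError(f"sign must be +/-1, got {s}")
            if b < 0:
                raise ValueError("effect size beta must be >= 0")

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _, _ in self.edges}

    def targets_of(self, regulator: str) -> list[tuple[str, int, float]]:
        return [(t, s, b) for r, t, s, b in self.edges if r == regulator]


@dataclass
class CohortTruth:
    """Which cohort samples carry which active planted regulons."""

    active_map: dict[str, set]
    delta: float
    benign_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for s in self.benign_ids:
            if self.active_map.get(s):
                raise ValueError(f"benign sample {s} has a non-empty active set")

    def active_samples(self) -> set:
        return {s for s, regs in self.active_map.items() if regs}


@dataclass
class SurvivalTruth:
    """Proportional-hazards ground truth for the survival stage."""

    true_hr: float
    baseline_rate: float  # events per month for the inactive group
    censor_time: float  # months of administrative censoring

    def __post_init__(self) -> None:
        if self.true_hr <= 0 or self.baseline_rate <= 0 or self.censor_time < 0:
            raise ValueError("true_hr and baseline_rate must be > 0, censor_time >= 0")


def generate_planted_network(
    n_regulators: int,
    targets_per_regulator: int,
    frac_negative: float = 0.0,
    overlap_frac: float = 0.0,
    seed: int = 0,
    beta: float = 1.0,
) -> PlantedNetwork:
    """Plant ``n_regulators`` regulons of fixed size with optional overlap.

    ``floor(overlap_frac * targets_per_regulator)`` of each regulon's targets
    are drawn from a shared pool (creating Jaccard overlap between regulons);
    the rest are private.  ``floor(frac_negative * targets_per_regulator)``
    edges per regulon are signed -1, the rest +1.  Deterministic per seed.
    """
    if n_regulators < 0 or targets_per_regulator < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= frac_negative <= 1 or not 0 <= overlap_frac <= 1:
        raise ValueError("frac_negative and overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    regulators = [f"TF{i:03d}" for i in range(n_regulators)]
    n_shared = int(np.floor(overlap_frac * targets_per_regulator))
    n_private = targets_per_regulator - n_shared
    # shared pool sized so regulons genuinely collide on it
    pool_size = max(n_shared * 2, n_shared)
    shared_pool = [f"SH{i:03d}" for i in range(pool_size)]
    n_neg = int(np.floor(frac_negative * targets_per_regulator))

    edges: list[tuple[str, str, int, float]] = []
    targets: list[str] = []
    seen = set()
    for i, reg in enumerate(regulators):
        private = [f"G{i:03d}_{j:03d}" for j in range(n_private)]
        shared = (
            list(rng.choice(shared_pool, size=n_shared, replace=False)) if n_shared else []
        )
        regulon_targets = private + shared
        signs = np.ones(len(regulon_targets), dtype=int)
        signs[:n_neg] = -1
        rng.shuffle(signs)
        for t, s in zip(regulon_targets, signs):
            edges.append((reg, t, int(s), float(beta)))
            if t not in seen:
                seen.add(t)
                targets.append(t)
    return PlantedNetwork(edges=edges, regulator_ids=regulators, target_ids=targets)


def _network_log2(
    network: PlantedNetwork,
    n_samples: int,
    sigma: float,
    rng: np.random.Generator,
    regulator_sd: float = 1.0,
    regulator_shift: np.ndarray | None = None,
    active_sets: list[set] | None = None,
) -> pd.DataFrame:
    """Log2 abundances of all network genes for ``n_samples`` columns.

    ``regulator_shift`` (per regulator) and ``active_sets`` (per sample)
    implement cohort activity: the shift is applied to a regulator's mean in
    exactly the samples whose active set contains it, and propagates to its
    targets through ``sign * beta``.
    """
    regs = network.regulator_ids
    reg_log2 = pd.DataFrame(
        BASELINE_LOG2 + regulator_sd * rng.standard_normal((len(regs), n_samples)),
        index=regs,
    )
    if regulator_shift is not None and active_sets is not None:
        for i, reg in enumerate(regs):
            mask = np.array([reg in s for s in active_sets])
            reg_log2.iloc[i, :] += regulator_shift[i] * mask
    rows = {reg: reg_log2.loc[reg].to_numpy() for reg in regs}
    # accumulate target means from all incoming edges (shared targets sum)
    tgt_dev: dict[str, np.ndarray] = {
        t: np.zeros(n_samples) for t in network.target_ids if t not in rows
    }
    for r, t, s, b in network.edges:
        if t in tgt_dev:
            tgt_dev[t] += s * b * (rows[r] - BASELINE_LOG2)
    for t, dev in tgt_dev.items():
        rows[t] = BASELINE_LOG2 + dev + sigma * rng.standard_normal(n_samples)
    order = regs + [t for t in network.target_ids if t not in set(regs)]
    if not order:
        return pd.DataFrame(np.empty((0, n_samples)))
    return pd.DataFrame(np.vstack([rows[g] for g in order]), index=order)


def _decoy_log2(
    n_decoys: int, n_samples: int, rng: np.random.Generator, low_expression: int = 0
) -> pd.DataFrame:
    """Independent background genes; optionally a block below the FPKM filter."""
    frames = []
    if n_decoys:
        frames.append(
            pd.DataFrame(
                BASELINE_LOG2 + rng.standard_normal((n_decoys, n_samples)),
                index=[f"DECOY{i:03d}" for i in range(n_decoys)],
            )
        )
    if low_expression:
        frames.append(
            pd.DataFrame(
                LOW_EXPRESSION_LOG2 + 0.1 * rng.standard_normal((low_expression, n_samples)),
                index=[f"LOW{i:03d}" for i in range(low_expression)],
            )
        )
    return pd.concat(frames) if frames else pd.DataFrame()


def simulate_expression(
    network: PlantedNetwork,
    n_samples: int,
    sigma: float = 0.5,
    seed: int = 0,
    n_decoys: int = DEFAULT_DECOYS,
    n_low_expression: int = 0,
    condition: str = "orthograft",
) -> ExpressionMatrix:
    """Training-style matrix: regulators Normal(5,1), targets coupled via beta."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    log2 = _network_log2(network, n_samples, sigma, rng)
    decoys = _decoy_log2(n_decoys, n_samples, rng, n_low_expression)
    log2 = pd.concat([log2, decoys]) if len(decoys) else log2
    samples = [f"S{i:03d}" for i in range(n_samples)]
    log2.columns = samples
    cond = pd.Series(condition, index=samples)
    return ExpressionMatrix(np.power(2.0, log2), cond)


def simulate_cohort(
    network: PlantedNetwork,
    active_regulators: set,
    n_tumour: int,
    n_benign: int,
    delta: float = 3.0,
    sigma: float = 0.5,
    active_fraction: float = 0.5,
    seed: int = 0,
    n_decoys: int = DEFAULT_DECOYS,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Tumour/benign cohort in which a fraction of tumours carry active regulons.

    Benign samples sit at baseline.  Each active tumour sample has every
    listed regulator shifted +delta log2 units, its targets following through
    ``sign * beta * delta``.  ``sigma`` is the per-gene noise sd (regulators
    and targets).  Returns the matrix plus a :class:`CohortTruth` recording
    which samples are active.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    unknown = set(active_regulators) - set(network.regulator_ids)
    if unknown:
        raise ValueError(f"active regulators not in network: {sorted(unknown)}")
    if n_tumour < 1 or n_benign < 2:
        raise ValueError("need >= 1 tumour and >= 2 benign samples")
    rng = np.random.default_rng(seed)
    tumour_ids = [f"T{i:03d}" for i in range(n_tumour)]
    benign_ids = [f"B{i:03d}" for i in range(n_benign)]
    n_active = int(round(active_fraction * n_tumour))
    active_idx = rng.choice(n_tumour, size=n_active, replace=False)
    active_sets: list[set] = [set() for _ in range(n_tumour)] + [set() for _ in benign_ids]
    for i in active_idx:
        active_sets[i] = set(active_regulators)

    n_samples = n_tumour + n_benign
    shift = np.full(len(network.regulator_ids), delta)
    log2 = _network_log2(
        network, n_samples, sigma, rng,
        regulator_sd=sigma, regulator_shift=shift, active_sets=active_sets,
    )
    decoys = _decoy_log2(n_decoys, n_samples, rng)
    log2 = pd.concat([log2, decoys]) if len(decoys) else log2
    samples = tumour_ids + benign_ids
    log2.columns = samples
    cond = pd.Series(["tumour"] * n_tumour + ["benign"] * n_benign, index=samples)
    truth = CohortTruth(
        active_map={s: active_sets[i] for i, s in enumerate(tumour_ids)},
        delta=delta,
        benign_ids=set(benign_ids),
    )
    return ExpressionMatrix(np.power(2.0, log2), cond), truth


def simulate_survival(
    truth: CohortTruth, surv: SurvivalTruth, seed: int = 0
) -> pd.DataFrame:
    """Exponential time-to-recurrence per tumour sample, censored administratively.

    Hazard is ``baseline_rate`` for inactive samples and
    ``baseline_rate * true_hr`` for active ones.  Also draws Gleason score
    and tumour stage as independent ordinal covariates for multivariate
    models.  Columns: sample, time_months, event, group, gleason, stage.
    """
    if not truth.active_map:
        raise ValueError("cohort has no tumour samples")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in sorted(truth.active_map):
        active = bool(truth.active_map[sample])
        rate = surv.baseline_rate * (surv.true_hr if active else 1.0)
        t = rng.exponential(1.0 / rate)
        event = 1 if t <= surv.censor_time else 0
        rows.append(
            {
                "sample": sample,
                "time_months": min(t, surv.censor_time),
                "event": event,
                "group": "active" if active else "inactive",
                "gleason": int(rng.integers(6, 10)),
                "stage": int(rng.integers(1, 5)),
            }
        )
    return pd.DataFrame(rows)
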