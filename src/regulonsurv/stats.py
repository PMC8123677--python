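"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def percentage(count: int, total: int, digits: int = 1) -> float:
    """Composition percentage as printed in clinical cohort tables."""
    if total <= 0 or count < 0 or count > total:
        raise ValueError("need 0 <= count <= total with total > 0")
    return round(100.0 * count / total, digits)


def composition_percentages(counts: dict, total: int | None = None) -> dict:
    """Percentages for a table of category counts (e.g. tumour stage)."""
    total = sum(counts.values()) if total is None else total
    return {k: percentage(v, total) for k, v in counts.items()}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
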