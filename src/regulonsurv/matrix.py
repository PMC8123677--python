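"""Core in-memory containers shared by every pipeline stage.

The substrate of the pipeline is an FPKM-like non-negative gene × sample
matrix with a condition label (tumour / benign / orthograft) per sample.
Inferred networks are held as an edge table (a tidy DataFrame) plus a
lightweight regulon view grouped by regulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("tumour", "benign", "orthograft")

#: canonical column order for edge tables throughout the package
EDGE_COLUMNS = ["regulator", "target", "sign", "mi", "p", "q"]


class EmptyMatrixError(ValueError):
    """Raised when a filter leaves no genes for downstream stages."""


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.  Values must
        be finite and non-negative (FPKM-like).
    condition
        Mapping from sample id to one of ``tumour``, ``benign``,
        ``orthograft``.  Every sample must be labelled.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")
        cond = pd.Series(self.condition)
        missing = [s for s in v.columns if s not in cond.index]
        if missing:
            raise ValueError(f"samples missing a condition label: {missing[:5]}")
        bad = set(cond.loc[list(v.columns)]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self.condition = cond.loc[list(v.columns)]

    # -- convenience views ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def samples_with(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.condition.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = list(samples)
        return ExpressionMatrix(self.values[keep], self.condition.loc[keep])


@dataclass
class Regulon:
    """One regulator and its signed target edges."""

    regulator: str
    targets: list[str]
    signs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"regulon {self.regulator} has no targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.regulator} has duplicate targets")
        if self.regulator in self.targets:
            raise ValueError(f"regulon {self.regulator} contains a self-loop")
        for t, s in self.signs.items():
            if s not in (-1, 1):
                raise ValueError(f"edge {self.regulator}->{t} has sign {s}")

    @property
    def size(self) -> int:
        return len(self.targets)

    def target_set(self) -> frozenset:
        return frozenset(self.targets)


class RegulonSet:
    """Regulons keyed by regulator id, backed by a tidy edge table."""

    def __init__(self, regulons: Mapping[str, Regulon]):
        for name, reg in regulons.items():
            if name != reg.regulator:
                raise ValueError(f"key {name!r} does not match regulator {reg.regulator!r}")
        self.regulons: dict[str, Regulon] = dict(regulons)

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "RegulonSet":
        regulons = {}
        if len(edges):
            for reg, grp in edges.groupby("regulator", sort=True):
                regulons[reg] = Regulon(
                    regulator=reg,
                    targets=list(grp["target"]),
                    signs=dict(zip(grp["target"], grp["sign"].astype(int))),
                )
        return cls(regulons)

    def to_edges(self) -> pd.DataFrame:
        rows = [
            {"regulator": r.regulator, "target": t, "sign": r.signs.get(t, 1)}
            for r in self.regulons.values()
            for t in r.targets
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "sign"])

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons.values())

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.regulons

    def __getitem__(self, regulator: str) -> Regulon:
        return self.regulons[regulator]

    def sizes(self) -> pd.Series:
        return pd.Series({r: reg.size for r, reg in self.regulons.items()}, dtype=int)

    def summary(self) -> dict:
        """Regulon-size summary logged by the assembly stage."""
        sizes = self.sizes()
        if sizes.empty:
            return {"n_regulons": 0, "median_size": None, "min_size": None, "max_size": None}
        return {
            "n_regulons": int(len(sizes)),
            "median_size": float(sizes.median()),
            "min_size": int(sizes.min()),
            "max_size": int(sizes.max()),
        }
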