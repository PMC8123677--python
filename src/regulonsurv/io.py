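"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated for diffability.  The edge-table dialect is
``regulator  target  sign  mi  p  q`` with sign written as ``+``/``-``;
regulon sets can additionally be exported as GMT (one line per regulon:
name, description, members), in which the sign information is lost.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import EDGE_COLUMNS, ExpressionMatrix, RegulonSet
from .survival import SignatureDefinition

logger = logging.getLogger(__name__)


# -- expression matrices ----------------------------------------------------


def write_expression_matrix(m: ExpressionMatrix, path, annot_path) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    annot = pd.DataFrame({"sample": m.samples, "condition": m.condition.to_numpy()})
    annot.to_csv(annot_path, sep="\t", index=False)


def read_expression_matrix(path, annot_path) -> ExpressionMatrix:
    """Expression TSV (first column gene id, header sample ids) + annotation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dupes[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    annot = pd.read_csv(annot_path, sep="\t")
    cond = pd.Series(annot["condition"].to_numpy(), index=annot["sample"].to_numpy())
    missing = [s for s in df.columns if s not in cond.index]
    if missing:
        raise ValueError(f"annotation {annot_path} is missing samples: {missing}")
    return ExpressionMatrix(df, cond.loc[list(df.columns)])


# -- edge tables and regulon sets ------------------------------------------

_SIGN_TOKENS = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}


def write_edges(edges: pd.DataFrame, path) -> None:
    out = edges.copy()
    for col in EDGE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out["sign"] = out["sign"].map({1: "+", -1: "-"})
    out[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sign": str})
    signs = []
    for tok in df["sign"].astype(str):
        if tok not in _SIGN_TOKENS:
            raise ValueError(f"malformed sign token {tok!r} in {path}")
        signs.append(_SIGN_TOKENS[tok])
    df["sign"] = signs
    return df


def write_gmt(rs: RegulonSet, path, description: str = "regulon") -> None:
    """GMT export: one tab-separated line per regulon (signs are lost)."""
    with open(path, "w") as fh:
        for name in sorted(rs.regulons):
            members = "\t".join(rs[name].targets)
            fh.write(f"{name}\t{description}\t{members}\n")


def read_regulons(path) -> RegulonSet:
    return RegulonSet.from_edges(read_edges(path))


def write_regulons(rs: RegulonSet, path) -> None:
    write_edges(rs.to_edges(), path)


# -- misc tables ------------------------------------------------------------


def read_regulator_list(path) -> list[str]:
    """One regulator id per line; blank lines ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {sorted(missing)}")
    return df


def read_signature(path) -> SignatureDefinition:
    """Signature TSV: columns gene, optional coefficient; name from filename.

    The split rule may be set via a ``# split: <rule>`` header comment,
    defaulting to percentile-67 (median when coefficients are present).
    """
    path = Path(path)
    split = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "split:" in first:
                split = first.split("split:", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    coefficients = df["coefficient"].tolist() if "coefficient" in df.columns else None
    if split is None:
        split = "median" if coefficients is not None else "percentile-67"
    return SignatureDefinition(
        name=path.stem, genes=df["gene"].tolist(), coefficients=coefficients, split=split
    )
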