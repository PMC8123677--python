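#!/usr/bin/env python
"""Per-sample differential expression of cohort tumours vs the benign panel.

One z-test profile per tumour on log2(FPKM + 1) against the pooled benign
mean/sd (BH-FDR 0.05, |log2FC| >= 1), plus the cohort-wide ranking of genes
by alteration frequency.
"""

import argparse
from pathlib import Path

import pandas as pd

from regulonsurv import deg as dg
from regulonsurv import io
from regulonsurv.config import PipelineConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
cfg = PipelineConfig(seed=args.seed).deg

cohort = io.read_expression_matrix(args.dir / "cohort_expression.tsv",
                                   args.dir / "cohort_annotation.tsv")
profiles = dg.cohort_deg_profiles(cohort, pseudocount=cfg.pseudocount,
                                  lfc_threshold=cfg.lfc_threshold, fdr=cfg.fdr)
degdir = args.dir / "deg_profiles"
degdir.mkdir(exist_ok=True)
for p in profiles:
    p.records.to_csv(degdir / f"{p.sample}.tsv", sep="\t", index=False)

summary = pd.DataFrame(
    [{"sample": p.sample, "n_up": p.n_up, "n_down": p.n_down} for p in profiles]
)
summary.to_csv(args.dir / "deg_summary.tsv", sep="\t", index=False)
ranking = dg.deg_frequency_ranking(profiles)
ranking.to_csv(args.dir / "deg_frequency_ranking.tsv", sep="\t", index=False)

print(f"{len(profiles)} tumour profiles vs {len(cohort.samples_with('benign'))} benign controls")
print(f"median up-regulated genes per sample: {summary['n_up'].median():.0f} "
      f"(range {summary['n_up'].min()}-{summary['n_up'].max()}); "
      f"median down: {summary['n_down'].median():.0f}")
print("most frequently altered genes:")
print(ranking.head(5).to_string(index=False))
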