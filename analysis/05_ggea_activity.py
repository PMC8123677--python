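#!/usr/bin/env python
"""Score per-sample regulon activity by gene-graph consistency enrichment.

Each tumour's de-regulation profile is matched against every regulon's
signed edges; permutation p-values (gene-label shuffle) with BH across
regulons within each sample call regulons active at FDR 0.05.  Regulons
are then ranked by activation frequency across the cohort.
"""

import argparse
from pathlib import Path

from regulonsurv import deg as dg
from regulonsurv import ggea as gg
from regulonsurv import io
from regulonsurv.config import PipelineConfig
from regulonsurv.pipeline import stage_seed

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
cfg = PipelineConfig(seed=args.seed)

rs = io.read_regulons(args.dir / "edges_filtered.tsv")
cohort = io.read_expression_matrix(args.dir / "cohort_expression.tsv",
                                   args.dir / "cohort_annotation.tsv")
profiles = dg.cohort_deg_profiles(cohort, fdr=cfg.deg.fdr)
activity = gg.activity_matrix(profiles, rs, fdr=cfg.ggea.fdr,
                              n_perm=cfg.ggea.n_perm,
                              seed=stage_seed(args.seed, "ggea"),
                              cap=cfg.ggea.cap)
activity.to_csv(args.dir / "activity.tsv", sep="\t", index=False)
freq = gg.activation_frequency(activity)
freq.to_csv(args.dir / "activation_frequency.tsv", sep="\t", index=False)

print(f"{int(activity['active'].sum())} active (sample, regulon) calls "
      f"out of {len(activity)} at FDR {cfg.ggea.fdr}")
print("activation-frequency ranking:")
print(freq.to_string(index=False))
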