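# regulonsurv

Regulon inference, per-sample regulon-activity scoring, and recurrence
survival analysis for FPKM-like expression cohorts.

A *regulon* is a transcription factor (TF) together with the target genes
it is inferred to regulate, each edge carrying a sign (activation or
repression). This package implements the full analysis path from an
expression matrix to prognostic regulons, for researchers studying
outcome-linked transcriptional programmes (the motivating setting is
prostate cancer and time to biochemical recurrence after prostatectomy):

1. **Network inference** — after an FPKM ≥ 1 expression filter and
   per-gene zero-one rescaling, each candidate regulator is tested against
   every other gene by mutual information,
   `MI = Σ p̂_ij ln( p̂_ij / (p̂_i p̂_j) )`, on equal-frequency bins
   (B = ⌈√n⌉), with a permutation null over the regulator's sample order
   and Benjamini–Hochberg correction within regulator. Indirect edges are
   pruned by the data-processing inequality (the weakest edge of every
   fully connected triple is removed), and edge signs come from the
   Spearman correlation of the two profiles.
2. **Shadow filtering and graph metrics** — regulons whose apparent signal
   is explained by target sharing with a stronger partner are removed by
   re-testing each member of a hypergeometrically surprising pair on its
   exclusive targets; the surviving graph is characterised by in-degree,
   betweenness, closeness, Burt's constraint, and Jaccard target overlap.
3. **Per-sample differential expression** — each tumour versus the pooled
   benign panel on log2(FPKM+1), one-sample z with a √(1+1/n) variance
   inflation, BH-FDR ≤ 0.05 and |log2FC| ≥ 1.
4. **Activity scoring** — a regulon's consistency with a sample's
   de-regulation profile is the mean over edges of
   `γ = (1 + sign · s_reg · s_tgt)/2` with capped scores
   `s = clip(log2FC/cap, −1, 1)`; significance by gene-label permutation,
   BH across regulons within each sample, active ⇔ q ≤ 0.05.
5. **Survival** — Cox proportional-hazards models (Efron ties, Wald CIs)
   of recurrence-free time on regulon activity, clinical covariates, and
   three formula-defined comparator signature scores (mean/67th-percentile,
   weighted-sum/median, and a rank-walk enrichment score), with
   Kaplan–Meier curves and logrank tests. Multivariate models are fitted
   only for univariately significant variables.

The original clinical cohorts are controlled-access, so the package ships
a first-class synthetic-data module that plants signed regulons in a
log2-normal expression model, activity shifts in a tumour/benign cohort,
and a true hazard ratio in exponential survival times — every stage has a
parameter-recovery test with known ground truth. See `docs/methods.md`
for the model and every default.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (default output under `results/analysis/`):

```sh
python analysis/01_simulate.py      --seed 1
python analysis/02_infer_network.py --seed 1
python analysis/03_graph_metrics.py --seed 1
python analysis/04_per_sample_deg.py --seed 1
python analysis/05_ggea_activity.py --seed 1
python analysis/06_survival.py      --seed 1
```

`01` plants 5 regulons × 20 signed targets among 200 background genes and
simulates 60 training samples, a 40-tumour/12-benign cohort in which the
`TF000` regulon is active in 20 tumours (Δ = 3 log2 units), and survival
times with a true hazard ratio of 6 for active samples. `02` prints the
recovery of that network:

```
candidate edges: 105; after DPI+signing: 103
regulons: 5 (median size 21.0, range 20-21)
recovery vs planted network: precision 0.971, recall 1.000
```

`05` ranks regulons by activation frequency — the planted regulon is
called active in exactly the 20 truly active tumours:

```
regulator  n_active  n_samples  frequency
    TF000        20         40      0.500
    TF003         3         40      0.075
```

and `06` produces the univariate Cox ranking and Kaplan–Meier contrast:

```
variable       hr   ci_low   ci_high        p  n  n_events
   TF000 6.655419 2.901547 15.265854 0.000008 40        38
   TF003 0.597644 0.180672  1.976946 0.399033 40        38
   TF002 1.043122 0.140646  7.736485 0.967060 40        38

top regulon TF000: logrank p = 5.8e-07 (active vs inactive patients)
```

The planted regulon ranks first with an estimated hazard ratio of 6.7
(true value 6; the Wald interval covers it), and no unplanted regulon is
significant. The same pipeline is available as a single command
(`regulonsurv run --seed 1 --out results/run`) and as stage-wise
subcommands (`simulate`, `infer`, `graph`, `deg`, `ggea`, `survival`) for
real data supplied as TSV matrices with a sample-annotation file.

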