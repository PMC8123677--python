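# Methods

`regulonsurv` re-implements, as one tested pipeline, a regulon-activity
analysis for prostate-cancer expression cohorts: signed transcription-factor
(TF) regulons are inferred from a training expression matrix, each tumour
sample is scored for regulon activity by how consistently the regulon's
signed edges agree with that sample's differential-expression profile, and
activity calls are related to time to biochemical recurrence with Cox
proportional-hazards models. Because the original clinical cohorts are
controlled-access, every stage is validated against synthetic data with
planted ground truth; the generator is first-class, tested code.

## Synthetic data model

Expression is log2-normal and FPKM-like. In the training (orthograft-like)
matrix a regulator's log2 abundance is Normal(mu=5, sd=1) and each target
follows

    log2(target) = 5 + sign * beta * (log2(regulator) - 5) + Normal(0, sigma)

with matrix entries `2**log2` (strictly positive). The baseline of 5 keeps
every simulated gene comfortably above the FPKM >= 1 expression filter; an
optional block of low-expression decoys (log2 mean -2) exists purely to
exercise that filter. Background ("decoy") genes are independent
Normal(5, 1); the default of 200 decoys gives permutation nulls a realistic
gene universe. Defaults: beta = 1 (1.5 in the inference power analysis),
sigma = 0.5, 60 training samples — chosen so a planted edge corresponds to
a regulator-target correlation of about 0.9, a regime in which a
sqrt(n)-bin mutual-information estimator has power at n = 60 but decoy
pairs do not.

In cohorts, regulon activity is a mean shift: an active tumour sample has
each active regulator raised by `delta` log2 units and its targets moved by
`sign * beta * delta`. Here `sigma` is the per-gene noise sd for
**regulators and targets alike**, so `delta/sigma` is the per-gene z-shift;
with the default delta = 3 and sigma = 0.5 an active regulon is strongly
but not trivially detectable after multiple-testing correction over the
~400-gene universe. (Fixing the regulator sd at 1 as in the training
matrix would make a 3-log2-unit shift borderline against a 400-gene BH
correction and per-sample activity calling could not reach the sensitivity
this package aims for; the cohort generator therefore treats `sigma` as
the noise scale of every gene.) Benign samples sit at baseline. Samples
are i.i.d.; library-size, composition and batch effects are deliberately
out of scope, so passing tests demonstrate statistical correctness of the
pipeline, not robustness to those artefacts of real RNA-seq.

Survival times are exponential — the simplest proportional-hazards model —
with hazard `lambda0` for inactive and `lambda0 * HR` for active samples
and administrative censoring. Defaults `lambda0 = ln2/24` per month (median
24 months in the inactive group), HR = 6, censoring at 60 months, matching
the hazard-ratio scale reported for regulon signatures in prostatectomy
cohorts. Gleason score and tumour stage are drawn independently of the
activity group, so multivariate adjustment has no planted confounding to
find.

## Network inference

1. **Expression filter**: keep genes with FPKM >= 1 in at least one sample.
2. **Zero-one rescaling** per gene, `(x - min)/(max - min)`; constant genes
   are dropped with a logged warning (the scaling is undefined for them).
3. **Mutual information**: equal-frequency discretisation into
   `B = ceil(sqrt(n))` bins per variable (ties broken by stable sort order,
   hence deterministic) and the plug-in estimator
   `MI = sum p_ij ln(p_ij/(p_i p_j))` in nats. This estimator was chosen
   for determinism and brute-force verifiability: tests compare it bin for
   bin with an independent contingency-table computation.
4. **Permutation test per regulator**: the regulator's sample order is
   permuted (default 1000 times) and MI recomputed against every other
   gene; `p = (1 + #{null >= obs})/(n_perm + 1)`; BH correction within
   regulator across targets, edges kept at q <= 0.05.
5. **DPI pruning**: in every fully connected triple of the undirected edge
   view, the weakest edge is removed when its MI is below
   `(1 - tolerance) * (middle MI)`; tolerance defaults to 0 and all triples
   are scanned before any removal, so scan order cannot matter.
6. **Edge signs** from the Spearman rank correlation of the two profiles
   (invariant to the monotone rescaling); edges with rho exactly 0 are
   dropped rather than arbitrarily signed. TF-TF edges are retained.

Numerical note on DPI power: the chain-recovery analysis (a planted
r -> m -> t cascade with no direct r -> t effect) is run at n = 400
samples and sigma = 1. At n = 60 the sqrt(n)-bin estimator's sampling
noise is comparable to the MI gap between the direct and indirect edges
and the weakest-edge ordering is unstable (~86% correct); this is a
resolution property of the estimator, not of the pruning rule, so the
chain analysis uses a sample size at which the ordering is estimable.

## Shadow filtering and graph metrics

A regulon can appear enriched purely because it shares targets with a
genuinely active regulator (the shadow effect). The published description
names the routine but not its algorithm, so this package uses an explicit,
testable substitute: for every ordered regulon pair (A, B) whose target
overlap is hypergeometrically surprising (p < 0.01 against the matrix's
gene universe), A is re-tested by the permutation MI test restricted to
targets exclusive to A; A is removed only when it retains no significant
exclusive target while B retains at least one. All pairs are judged on the
input set before any removal, making the filter order-independent and
idempotent, and a regulon with at least one significant exclusive target
can never be removed.

Node metrics: in-degree; betweenness and closeness on the directed graph,
with closeness defined as the inverse of the summed distance to reachable
nodes only (directed GRNs are rarely strongly connected, so the
reachable-set convention is required and is logged); Burt's constraint on
the undirected view with uniform weights (the measure presumes mutual
ties), isolated nodes reported as 0. Regulon overlap uses the Jaccard
index with the conventional 0.1 reporting threshold. All four metrics are
tested against exhaustive path-enumeration / direct-summation oracles on
random graphs of up to 20 nodes.

## Per-sample differential expression

Each tumour is compared with the pooled benign panel of its cohort on
log2(FPKM + 1): the panel supplies per-gene mean and sd (ddof = 1), and
the tumour value is scored with a one-sample z statistic inflated by
`sqrt(1 + 1/n_benign)` for the plug-in mean. The published analysis does
not name its per-sample test; this z-test is the simplest defensible
choice and is stated in every output header. Two-sided normal p-values are
BH-adjusted over all tested genes; calls require q <= 0.05 **and**
|log2FC| >= 1 (the fold-change reading of "at least one log2 unit";
configurable). Genes constant in the benign panel cannot form a z-score
and are excluded from testing, listed separately. Pseudocount 1.0,
configurable.

## Regulon activity (consistency enrichment)

The cited enrichment method is used with "default parameters" in the
original analysis; its internals are therefore explicit, documented
choices here, each switchable in configuration:

* **Fuzzy membership**: `s = clip(log2FC / cap, -1, 1)` for genes passing
  the DEG q-gate, else 0; cap defaults to 3 log2 units (an 8-fold change
  saturates the score).
* **Edge consistency**: `gamma = (1 + sign * s_reg * s_tgt)/2`, which is 1
  for concordant saturated pairs, 0 for discordant ones, and 0.5 when
  either gene carries no signal — unscored genes neither support nor
  contradict a regulon.
* **Aggregation**: regulon score S = mean gamma over edges, so S is
  monotone in each edge's concordance.
* **Null**: the gene -> score assignment is permuted uniformly over all
  scored genes (default 1000 draws, shared across regulons within a
  sample); `p = (1 + #{S_null >= S_obs})/(n_perm + 1)`. The null shares
  the 0.5 neutral baseline, keeping the test centred.

BH is applied across regulons within each sample (per-sample enrichment
framing); cross-sample correction is a non-goal. A regulon is *active* in
a sample iff q <= 0.05. Tiny instances are tested against exhaustive
enumeration of all score-to-gene assignments.

## Survival analysis

Biochemical recurrence is a PSA rise >= 2 ng/mL above the running nadir;
the event fires at the first such observation, otherwise the subject is
censored at the last one. Cox models use the Efron tie convention with
Wald 95% intervals (fits are cross-checked against a dense grid search of
an independently coded Efron partial likelihood); constant covariates and
zero-event data raise an explicit degenerate-fit error. Kaplan-Meier
curves use the product-limit estimator with a two-sided logrank test
across groups. Gleason and stage enter models as ordinal numerics
(T1-T4 -> 1-4), matching the one-hazard-ratio-per-variable table layout.

Comparator signatures are formula-defined; the published gene lists and
coefficients are not printed in the source analysis and are supplied by
the user as signature files (the test suite uses synthetic stand-ins):

* mean expression over signature genes, split at the 67th percentile
  (linear-interpolation quantile; ties to the low group);
* coefficient-weighted sum, median split;
* a rank-walk enrichment score (running sum gaining rank-weighted
  increments at set genes, default exponent tau = 0.25) — an
  approximation of single-sample GSEA-style scoring, not a bit-exact
  reimplementation of any particular tool.

The univariate report ranks regulons by Cox p; multivariate models
(variable + Gleason + stage) are fitted only for variables univariately
significant at alpha = 0.05, mirroring the gating of the published tables.
With ~30 subjects and ~50% events, power at HR = 6 is limited; the
acceptance script reports the estimated quantities rather than asserting
small-sample power.

## Problem sizes and reproducibility

Default end-to-end configuration: 5 regulons x 20 targets, 200 decoys, 60
training samples, 40 tumour + 12 benign cohort samples, 1000 permutations
in inference and enrichment — sizes at which every stage's statistical
behaviour is measurable while a full run completes in well under a minute
on one CPU. The null-calibration analyses use 25-50 replicate cohorts and
100-200 replicate survival datasets. All randomness flows from a single
seed through named per-stage substreams (a stage-name-hashed offset), so
changing one stage's parameters never shifts another stage's draws, and
re-running a configuration reproduces every output byte for byte (the run
manifest records seeds, config and output checksums).

## Known limitations

* The MI estimator's plug-in bias grows with bin count; comparisons are
  always within-estimator (permutation nulls, DPI orderings), never
  absolute MI values.
* The per-sample z-test assumes approximate log-normality of FPKM within
  the benign panel and ignores gene-gene correlation within a sample's
  BH correction.
* The generator's i.i.d.-sample assumption means cell-line or patient
  substructure (and any batch effect) is untested.
* The shadow filter and the enrichment internals are documented
  substitutes for routines whose published descriptions are nominal; they
  are validated against their own specifications, not against the
  original implementations.
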