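# Methods

This note documents the models and numerical choices behind `lncmod`: what
each stage assumes, which knobs matter, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Study container and stratification rules

An `ExpressionStudy` holds a genes × samples log2 intensity matrix (assumed
already normalized), a gene annotation (biotype ∈ {lncRNA, PCG, miRNA},
optional sense/antisense or locus partner), and per-sample clinical
metadata. Input ordering is preserved everywhere; nothing is silently
sorted or imputed — analyses that need complete covariates drop incomplete
patients case-wise and log the count.

Stratifiers return partitions (disjoint, exhaustive over the input):

- **18-month overall-survival split.** Short survivors are patients who
  died at ≤ 18 months (death at exactly the cut-off counts as short); long
  survivors are anyone followed beyond 18 months. Patients censored at or
  before the cut-off carry no usable label and are excluded — assigning
  them to either stratum would bias the contrast; this exclusion rule is a
  documented choice, and the cut-off is configurable.
- **IPSS-R split.** Lower risk = {very_low, low}, higher = {high,
  very_high}; intermediate-risk MDS, AML-MRC and controls are excluded.
  Scores map to categories at the conventional ≤1.5 / ≤3 / ≤4.5 / ≤6
  breakpoints, and the container validates score/category consistency.
- **Mutation carriers.** A sample carries a mutation iff any recorded
  variant in the gene exceeds 5% VAF *strictly* — a variant at exactly
  0.05 is wild type. Unscreened samples (no mutation data at all) are
  excluded from both sets; "screened with no variants" is distinct from
  "not screened" in the file format (`none` vs an empty cell).

## Differential expression

The moderated t follows the standard empirical-Bayes construction: a
scaled-inverse-χ² prior on the true residual variances, giving the
posterior `s2_post = (d0*s2_0 + d_g*s2_g)/(d0 + d_g)` and a t statistic on
`d0 + d_g` df. Hyperparameters come from the method of moments on
`z = log s2`: the mean of `z − digamma(d/2) + log(d/2)` identifies `s2_0`,
and the excess of its variance over `trigamma(d/2)` identifies `d0` through
a trigamma inverse (Newton iteration). When the excess is non-positive the
prior df is infinite and all genes share one variance; in that branch
`s2_0` is the arithmetic mean of the observed variances — the natural
estimate when all true variances coincide, and the choice that makes a
constant-variance input an exact fixed point of the shrinkage (the
log-scale back-transform `exp(mean log s2)` would bias it low). A single
gene falls back to the ordinary pooled t with a warning.

Multiple testing is Benjamini–Hochberg step-up throughout. Significance
calls use strict inequalities at both thresholds; the default contrast
setting is |logFC| > 1, FDR < 0.05, with a refined |logFC| > 0.3 variant
for mutation contrasts whose expression effects are subtler.

The detection filter keeps genes exceeding a signal floor (default: the
matrix 10th percentile) in ≥ 10% of samples; both knobs are exposed because
they stand in for an array-specific detection call. Probe rows sharing a
gene id collapse to their per-sample median.

One-way ANOVA across the diagnostic groups uses the classical F statistic
(vectorized over genes), BH across genes, and expresses group means as
log2 fold changes against the control mean. Group clustering operates on
the group-mean fold-change vectors restricted to ANOVA-significant genes
(average linkage, Euclidean, cut to k = 3 by default) — clustering group
profiles rather than individual samples matches the eight-group summary
layout this analysis feeds.

## Enrichment

The GSEA enrichment score walks the ranking (descending score, ties broken
by gene id for determinism), adding `|r|^p / Σ_hits |r|^p` at members and
subtracting `1/(N − N_H)` at non-members; ES is the extremum of largest
magnitude and `p = 1` by default (`p = 0` reduces to the classical
Kolmogorov–Smirnov statistic). Significance uses phenotype (sample-label)
permutations, which preserve inter-gene correlation, with the moderated t
recomputed per permutation as the ranking metric (configurable to
signal-to-noise). Groups smaller than 7 fall back to permuting scores
across genes with a warning; fewer than 20 distinct label assignments
triggers exact enumeration. NES divides ES by the mean |permuted ES| of the
same sign; the permutation p is one-sided within that sign pool
(with the +1 smoothing), and FDR is BH within the positive and negative
pools separately — a pragmatic simplification of the original NES-pooling
scheme, adequate at the collection sizes used here.

Module annotation is upper-tail hypergeometric over-representation of each
term among a module's PCG members, with the DE PCGs of the network as the
universe. Terms are reported at raw p < 0.01 (the guilt-by-association
convention for transferring PCG annotation to module lncRNAs); BH-adjusted
values are emitted alongside for transparency.

## Coexpression modules

The network pipeline takes the DE transcripts of a contrast (FDR < 0.05),
computes their Pearson correlation over the contrast's sample union
(Spearman optional — the choice is exposed because either is defensible),
symmetrizes exactly, and maps to a nonnegative matrix. The default
transform is positive clipping `max(C, 0)`: modules are meant to collect
*similarly regulated* genes, and the absolute-value transform would merge
anti-correlated genes into one module. `abs` and `(C+1)/2` remain available
for sensitivity analysis.

Factorization is multiplicative-update NMF on ‖A − WH‖²_F from uniform
random starts (best of 30 restarts by default, max 2000 iterations,
relative-change tolerance 1e-6). The update keeps the objective
non-increasing; the per-iteration trace is recorded and asserted in tests.
Membership is read from the column-normalized (unit-norm) symmetrization
`(W + Hᵀ)/2`; each gene goes to its argmax module, ties resolved to the
first module index and member ordering to lexicographic gene id, so builds
are deterministic. Module cores are the top 4 lncRNAs and top 13 PCGs by
membership.

Rank selection builds, per candidate k, a consensus matrix of co-assignment
frequencies over restarts and scores it by the cophenetic correlation of
its average-linkage dendrogram. On cleanly blocked matrices the consensus
can be perfectly stable for several ranks at once (merging two blocks the
same way on every restart is also "stable"), so candidates within 0.01 of
the maximum cophenetic value are re-ranked by reconstruction-error gain
over the next-smaller rank, which lands on the true block count in planted
tests. A maximum cophenetic below 0.9 flags the selection as low
confidence. Caveat: this flag measures restart stability on one fixed
matrix; a single realization of pure noise has real (random) block
structure and can factorize stably, so the flag detects structureless
inputs, not noise per se.

The lncRNA-centred variant seeds the gene list with designated focus
lncRNAs plus each focus's 50 most strongly |r|-correlated DE PCGs, runs the
same pipeline, and keeps only modules containing a focus, reporting which
foci co-occupy a module.

## Survival

Kaplan–Meier is the textbook product-limit estimator (censoring shrinks
the risk set without a step). The log-rank test sums observed-minus-
expected events over pooled event times with the hypergeometric variance;
zero variance returns p = 1 with a warning rather than an error.

The Cox model maximizes the Efron-tie partial likelihood by Newton–Raphson
on the analytic score and observed information (covariates centered for
conditioning; convergence at max |score| < 1e-8, cap 50 iterations, step
halving on likelihood decrease). Efron rather than Breslow because it is
the less biased default under ties and costs nothing here. Monotone
likelihood (separation) is detected either by a diverging Newton path or by
a converged coefficient exceeding 20 on the per-SD log-hazard scale — a
magnitude no real effect reaches — and raises an error naming the variable.
Wald CIs are `exp(β ± 1.96·se)`.

Backward elimination refits after dropping the variable with the largest
Wald p > 0.05 (`alpha_stay`, configurable), ties broken by dropping the
later input position; the removal trace is returned and the final summary
can be sorted by descending p. Removing every variable yields an empty
model with a warning, not an error. Univariate forest tables enter
continuous variables per unit into one-covariate Cox fits for the HR but
take the p-value from a log-rank test on the median split (binary
indicators are compared directly), starred at 0.05/0.01/0.001/0.0001.
Multivariate models standardize continuous covariates by default;
dichotomized entry is available — which form a given cohort analysis should
use is a genuine modelling choice, so both are exposed. Expression
dichotomization defaults to the median (ties to the low group), with a
maximally-selected log-rank cutpoint bounded to the 10–90% quantiles as an
option. The lower-risk sub-analysis filters to IPSS-R score < 4.5 before
re-running backward selection.

## Concordance / cis analysis

Cis-pair coregulation is Spearman correlation per pair per subgroup
(average ranks, t-approximation p on n − 2 df; subgroups under 4 samples
yield NaN). The discordance classifier works on linear-scale ratios
`2^(x−y)`: the reference ratio is the *median over healthy controls* — the
baseline had to be fixed somewhere, the control median is the least
assumption-laden choice, and a cohort-median alternative is configurable.
A sample is discordant iff its ratio departs from the reference by strictly
more than 10-fold in either direction (> 10 or < 0.1); exactly 10-fold is
concordant. The rule is symmetric in the pair and invariant to adding a
constant to both genes' log2 values, both asserted as properties.
Discordant vs concordant patients are compared by log-rank on OS and PFS.

## Synthetic-data generator

Expression follows
`x_gs = mu_g + Σ_c delta_gc·severity(group_s) + Σ_m lambda_gm·f_ms + eps_gs`
with `f ~ N(0, module_factor_sd²)`, `eps ~ N(0, noise_sd²)`,
`mu ~ N(7, 1.5²)` on the log2 scale. Defaults emulate the target study
design: ~10⁴ lncRNA + ~10⁴ PCG features; a discovery cohort of 9 controls,
54 MDS patients across six WHO subtypes and 14 AML-MRC (77 samples, with a
106-sample validation-cohort layout available as a constant); group effects
scaled by a severity score that puts single-lineage dysplasia near controls
(0.15), the intermediate subtypes at 0.5–0.6 and MDS-EB2/AML-MRC at 1.0 —
producing the gradual healthy → advanced expression shift and three natural
sample clusters. Planted DE genes get ±`de_logfc` (default 1.5, fraction
1%); module members additionally get a group effect so they pass the DE
filter feeding the network. Mutation screening marks 4 patients and 1
control unscreened (64 screened patients of 68) and plants carriers at the
studied frequencies (SF3B1 14, TET2 10, TP53 10, DNMT3A 9, RUNX1 9), each
mutation shifting 30 genes by ±0.6 in carriers — the refined-threshold
regime. Named locus genes (H19/IGF2/miR-675, WT1/WT1-AS, LEF1/LEF1-AS1,
TCL6/TCL1A/TCL1B) share per-locus latent factors (loading 1.5 over unit
factor against 0.5 residual noise, giving cis correlations near 0.9), and
the imprinted locus is disrupted with severity: H19 +2·sev, IGF2 and
miR-675 −2·sev, so advanced patients exceed the 10-fold discordance rule
while intermediate ones do not.

Survival is exponential with rate
`baseline_hazard · exp(Σ β_g z_gs)` (baseline 0.03/month ⇒ median ≈ 23
months untreated, a plausible higher-risk figure), `z` the standardized
marker expression; default markers H19 (β = 0.7), blast percentage (0.5)
and TP53 carriage (0.7), mirroring the dominant clinical predictors.
Censoring is an independent exponential whose rate is solved numerically so
the expected censored fraction equals `censor_rate` (default 0.3);
progression-free survival superimposes an independent progression process
(combined rate 1.6× death). The constant baseline hazard buys closed-form
sanity checks at the cost of realism in the hazard shape.

Annotation: each planted module gets one matched term covering
`term_enrichment` (default 0.8) of its members, plus 200 background terms
of 10–50 uniformly drawn genes; planted up/down gene sets are emitted as
GMT entries for GSEA recovery.

What the generator does **not** emulate: probe-level array chemistry and
normalization artefacts, batch effects, heavy-tailed or count-based noise,
correlated clinical confounding beyond the severity score, informative
censoring, and competing risks. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to those real-data pathologies.

All draws flow from `numpy.random.default_rng` seeded by
`SeedSequence([seed, stream])` with separate streams for expression,
survival and annotation, so runs are bit-reproducible per seed.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: cohort bookkeeping on the default 77-sample
layout (200+200 genes); DE null calibration over 50 replicates of 200
genes at 10 vs 10; DE recovery with 30 planted genes at |logFC| = 2,
20 per group; GSEA recovery at 500 permutations and null calibration over
200 random sets at 400 permutations; module recovery over 10 replicates of
the 3-module / 165-gene / 60-sample design (noise 0.3) plus one consensus
rank selection; Cox coverage over 500 fits at n = 150, coefficient
recovery over 100 fits at n = 500, backward selection over 30 replicates
at n = 400 with three noise covariates; and one end-to-end 4 010-gene
cohort for cis correlations, discordance and the multivariate model.
These sizes keep the full run around a minute on one CPU while leaving
every Monte-Carlo estimate stable to the reported precision.

## Known limitations

- The eBayes fit assumes a common residual df across genes (true for the
  balanced two-group contrasts it serves).
- GSEA FDR is BH within sign pools rather than the original
  permutation-NES pooling; q-values are slightly conservative.
- NMF multiplicative updates find local optima; restarts mitigate but do
  not guarantee the global factorization.
- The maximally-selected cutpoint search reports the minimizing p without
  a multiple-testing correction and is meant for exploration, not
  inference.
- Backward selection inherits the usual caveats of stepwise procedures;
  retained-variable p-values are not adjusted for the selection path.
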