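# Methods

`prgbm` analyzes patient-matched primary–recurrent (P–R) glioblastoma pairs:
how far the recurrent tumor has drifted from its primary, whether that drift
scales with the time to relapse (TTR), which genes are *stable* across the
pair yet prognostic in the primary tumor, and how well a Cox risk score built
from such genes predicts progression-free survival (PFS).  This note records
the models, the defaults, and the judgment calls.

## Cohort and covariate model

A cohort is a set of pairs, each with two expression profiles (TPM), clinical
covariates (age, gender, data source, IDH/MGMT/TMZ/resection status), a TTR
in months, a PFS interval (PFI) with an event indicator, per-sample variant
calls and a tumor mutation burden (TMB, mutations/Mb).  The analysis subset
is IDH wild-type pairs with complete age/gender/data-source/TTR information;
TTR strata are ≤ 6, 7–12, and > 12 months.

Expression preprocessing: genes kept when TPM > 0 in strictly more than half
of all samples; values are log2(TPM+1); covariates are removed per gene by
ordinary least squares.  Two residual sets are produced and used deliberately:

* **pair-adjusted** (age + gender + data source + pair identity): input for
  paired differential expression and per-pair RMSE.  Because age, gender and
  data source are constant within a pair, they are aliased with the pair
  dummies; residuals are computed by pseudoinverse projection, which is
  unique under the aliasing, and the aliased blocks are logged.
* **patient-level** (age + gender + data source only): input for everything
  that compares or correlates pair members, or predicts from the primary
  tumor.  Regressing out pair identity demeans within pairs, making the two
  members exact mirror images (correlation −1, primary value = half the
  within-pair difference); any similarity or survival analysis on such
  residuals is degenerate, so those analyses must never see the pair block.

The covariate scan tests each of six covariates (progression status, TTR,
age, gender, data source, pair identity) with a partial F-test of its dummy
block against the model holding the others, BH-adjusted across genes.
Pair-level covariates are tested in the model without the pair block (they
are not estimable beside it); this is recorded in the scan result.

## Divergence statistics

* Per-pair RMSE: root mean square of recurrent-minus-primary residuals over
  genes.
* Paired DE: per gene, OLS of pair-adjusted residuals on progression status
  within a TTR stratum; the log2 fold change is the mean difference (the
  data are already log-scale), p from the slope t-test, BH FDR across genes.
* TMB contrast: two-sided Wilcoxon signed-rank on paired TMB, Pratt handling
  of zeros.  Identical vectors report p = 1 with a warning (no evidence, not
  an error).
* Mutation-class ratio: with `a` primary and `b` recurrent calls surviving
  the alt-read filter (> 2 supporting reads), a one-proportion Z test of
  a/(a+b) against 0.5.
* Hypermutation at recurrence: ≥ 10 coding mutations gained and recurrent
  burden strictly > 10 coding mutations per targeted Mb.

## Transcriptome-overlap similarity (TROM)

Each sample's associated-gene set is the genes whose within-gene z-score
across samples exceeds 1.5 (the method's published default, exposed as a
parameter).  A sample pair is scored by −log10 of the BH-adjusted upper-tail
hypergeometric probability of their set overlap given the set sizes and gene
universe, capped at 300.  The pairing test compares the median score over
true pairs against medians over random re-pairings (two distinct samples per
pair, sampled without replacement per replicate); p-values use the add-one
estimator (1+k)/(1+N) and are bit-reproducible given a seed.

A structural caveat: under a *global* null in which every sample is
exchangeable, almost all adjusted overlap p-values equal 1, so the score
matrix is mostly exactly 0 and the median over true pairs is 0 with
probability near 1 — every permuted median is ≥ the observed one and the
test reports p = 1.  The pairing test is therefore conservative on data with
no pairing signal at all; it cannot be anti-conservative.  Its rejection
rate under such a null is ~0, not the nominal level.

## PC1 / TMB regression fits

Each sample is summarized by its score on the first principal component of
the gene-centered sample × gene matrix (sign fixed so the largest-magnitude
loading is positive; sign flips would not change any RMSE after refitting).
Recurrent summaries are regressed on primary summaries by OLS; each TTR
group's fit quality is the RMSE of its points about the *global* line,
`sqrt(mean (y_i − (β0 + β1 x_i))²)`.  The permutation null draws same-size
random pair subsets from the full cohort and asks, one-sided, whether the
observed group RMSE is small.  The same machinery runs on paired TMB.  This
null is well calibrated (rejection ≈ 0.05 on exchangeable data).

## Relapse-gene cascade

A gene is TTR-associated when, in order:

1. it is **not** differentially expressed between pair members in the ≤ 6
   month stratum (unadjusted p > 0.05 — stability in fast relapsers);
2. its primary and recurrent values correlate across pairs (Pearson
   p < 0.05), computed on patient-level residuals;
3. it is prognostic in the primary tumor: Kaplan–Meier log-rank on a median
   split **and** univariate Cox on the continuous value, both p < 0.05,
   endpoint PFI with the relapse indicator as event (the median split is the
   default dichotomization; the rule is configurable);
4. it is protein-coding and present in both the training matrix and a
   supplied external testing matrix (membership in the already-filtered
   matrices; no second expression threshold is applied).

Criteria run lazily in cascade order; survival fits are only spent on
criteria-1–2 survivors.  Two comparator first-criteria are implemented
behind the same interface: `deg` (gene is a DEG over all pairs, FDR < 0.05)
and `pfi_corr` (primary expression vs PFI, |r| ≥ 0.2 and p < 0.01).

## Consensus subgrouping and subtype calls

Consensus clustering is the Monti resampling scheme: 1000 resamples of 80%
of samples without replacement, k-means (k = 2 by default) on standardized
selected-gene expression per resample, consensus matrix = co-clustering
frequency among co-sampled replicates, final labels by average-linkage
hierarchical clustering of 1 − consensus.  On exactly identical samples any
partition is equally optimal, so consensus values are arbitrary there; the
implementation does not special-case that degenerate input.

Subtype calling scores each sample against named gene sets (classical /
proneural / mesenchymal signatures, supplied by the user as a GMT-style
file — the published lists are not redistributed here) with a single-sample,
rank-based enrichment statistic: the maximum deviation of a weighted
running sum over the sample's descending expression ranking, hit weights
(rank)^0.75, misses uniform.  Because it is rank-based, any strictly
monotone transform of the expression values leaves scores unchanged.  The
empirical p-value compares the score against random same-size gene sets;
that null depends only on the universe size and set size, so one null sample
serves all samples.  A sample gets the subtype with the lowest p; ties go to
the higher enrichment score.  Transition tables count
non-mesenchymal→mesenchymal and reverse transitions per TTR group, with a
one-proportion Z test of direction and Fisher tests of composition.

## Prognostic model

All Cox fits use lifelines' partial likelihood with Efron tie handling.
Stepwise selection is bidirectional: at each step the candidate with the
smallest likelihood-ratio entry p joins if p < sle (= 0.05), then any member
with Wald p > sls (= 0.05) leaves, worst first, iterating to a fixed point
with a step cap and cycle guard; ties break on candidate order, making the
procedure deterministic.  (The entry test is the LR statistic rather than a
score test; they are asymptotically equivalent and LR is what the fitting
library exposes.)

The risk score is `exp(Σ coefficient_i × expression_i)` over the model's
genes on covariate-adjusted expression — computed exactly, never
re-normalized.  Patients are high-risk iff score ≥ cutoff; the shipped
published seven-gene model (SIGLEC14, GHRHR, TAS2R1, CDKL1, ZSCAN10, TBX15,
CD101 with coefficients 0.3296, 0.2804, 2.1475, −0.7833, 0.8261, 0.5557,
−0.4108 and cutoff 1.04, the training-cohort median) lets external cohorts
be scored without refitting.  Evaluation: KM/log-rank on the dichotomized
groups; horizon AUC at 12/24/36 months with the plain binary rule (patients
censored event-free before the horizon are excluded; an IPCW Uno-type AUC is
available behind a flag); Harrell's C-index; and a nomogram export that
rescales each gene's coefficient × observed-range span to a 0–100 point axis
and maps total points to 1/2/3-year PFS through the Breslow baseline
survival.

## Synthetic cohort generator

The generator is the test bed; its defaults describe an 87-pair IDH-wt-like
cohort and are illustrative magnitudes, not fitted values.  Per gene g and
pair i, log2 expression is

    latent = μ_g + a_g·z(age) + g_g·[male] + s_g,source + b_gi (pair baseline)
    primary   = latent + programs_P + N(0, σ_noise²)
    recurrent = latent + programs_R + δ_gi + N(0, σ_noise²)

with δ_gi ~ N(0, σ_drift² · TTR_i) for drift genes (a random walk in time —
the divergence-grows-with-TTR hypothesis in generative form) and δ = 0
otherwise.  "Programs" are a low-rank component: genes load on 10 latent
co-expression programs whose activities are drawn per *sample*; without it,
independently drawn genes make the TROM score matrix identically zero (no
co-expression, no overlap signal), which no real transcriptome resembles.
Program activities of the two biopsies of a pair correlate at 0.7, decaying
exponentially with TTR (0.04/month): composition, like per-gene expression,
drifts with elapsed time.  Per-gene program variance is σ_program² = 0.64,
comparable to the noise variance.

Relapse times are exponential under proportional hazards: rate
0.07·exp(βᵀx_i) per month, where x_i is the pair's standardized primary
expression of the planted signature genes (default eight genes, β = ±0.5);
0.07 puts the median TTR near 10 months.  Censoring is independent
exponential (0.01/month).  TMB: primary ~ Gamma(4, 0.5) (≈ 2 mut/Mb);
recurrent adds 0.08/month of TTR plus noise, floored at 0.  Variant tables
draw per-class Poisson counts scaled by burden, with ~10% of calls placed at
or below the 2-read support threshold so the alt-read filter is exercised.
TPM is 2^x − 1 floored at 0.  One integer seed feeds named sub-streams;
identical configurations are bit-identical.

The **null cohort** zeroes drift, signature effects, the TMB slope, all
covariate effects, the shared pair baseline, and the within-pair program
correlation, making every sample an i.i.d. draw — the exchangeability that
permutation-test calibration requires.  Note the marginal single-gene hazard
signal in a generated cohort is attenuated by the other signature genes
(they act as frailty); recovery experiments should use moderate total
linear-predictor variance.

What the generator does **not** emulate: read-level data, copy number,
single-cell structure, heavy-tailed count noise, gene-length effects, or
subtype-structured (multimodal) composition.  Passing tests therefore show
the pipeline's statistics behave correctly under the stated generative
assumptions — monotone drift, proportional hazards, exchangeable nulls —
not that real cohorts satisfy those assumptions.

## Problem sizes used in tests

The shared test cohort is 60 pairs × 400 genes; calibration runs 200 null
cohorts of 60 pairs × 2000 genes with 1000 permutations each; divergence
recovery uses 300 pairs; stepwise recovery 50 cohorts of 400 pairs with one
planted gene among 20 noise genes; the end-to-end smoke run is 100 pairs ×
2000 genes.  These sizes keep the full suite in the tens of minutes on one
CPU while leaving every assertion at the scale its statistic needs.
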