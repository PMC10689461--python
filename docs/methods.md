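# Methods

`bileflow` analyses the bile proteome collected during sequential
hypothermic machine perfusion, controlled rewarming and normothermic
machine perfusion (NMP) of human donor livers. Its stages mirror how
such studies are analysed in practice; every stage is exercisable on a
synthetic cohort with planted ground truth, so the statistical machinery
can be validated without access to any deposited raw data.

## Clinical scoring

**Biliary viability (traffic-light) score.** Each bile-chemistry
criterion (e.g. bile pH, bicarbonate, glucose, bile/perfusate glucose
ratio, measured at the 150 min viability assessment) has a green and an
orange boundary in its own units and a direction. A measurement earns
2 points in the green band, 1 in the orange band, 0 in the red band; the
per-liver sum is the biliary viability score. Values exactly on a
boundary take the better colour — the boundary value itself "meets" the
criterion; the comparison direction is configurable per criterion. A
missing measurement defaults to red (a liver producing no assessable
bile fails that criterion) with a warning; a hard-error policy is
available. Livers are classed high/low either by a fixed point threshold
(default 5 of 8 with the four bundled criteria) or by copying the
clinical transplant decision; both rules exist because published cohorts
are ambiguous about which definition their stratified figures use.

**Histological bile-duct injury (BDI).** Four ordinal components —
vascular lesions, stromal necrosis, periluminal peribiliary-gland (PBG)
injury, deep PBG injury — are summed into a total BDI score only when
all four are gradable (per-component scale configurable, default 0–4).
The cohort median of gradable totals splits livers into high and low
BDI; totals exactly at the median go to the high-injury group by
default (`tie_to_high=False` flips only those livers).

## Intensity-matrix preprocessing

The pipeline starts from the protein-group quantitation matrix of a
DIA search (proteins x samples, tab-separated, explicit missing cells).

1. **log2 transform** of raw intensities (guarded against double
   transformation).
2. **Valid-value filter**: a protein is kept only if quantified in at
   least a threshold fraction of the samples of *every* timepoint
   (inclusive comparison; default 0.40). A `derive` helper reports the
   cohort median presence and rounds it down to the nearest 5% for
   studies that tie the cutoff to observed presence.
3. **Downshifted-normal imputation**: each missing cell is drawn from
   Normal(mu − downshift*sd, (width*sd)^2) with mu, sd the mean/SD
   (ddof=1) of observed values in the scope. Defaults width 0.3,
   downshift 1.8, per-sample scope — the de-facto standard parameters
   for this imputation in proteomics software. Whole-matrix scope and
   both impute-before/after-batch-correction orders are supported since
   published pipelines rarely state either choice. Observed cells are
   never altered; the draw is seeded.
4. **Batch correction** with the parametric empirical-Bayes ComBat
   model: standardize per protein against the batch-size-weighted grand
   mean and pooled variance, estimate per-batch location/scale effects,
   shrink them toward across-protein priors (normal / inverse-gamma),
   remove, back-transform. The implementation reproduces the R `sva`
   reference to ~1e-14 on random matrices (a cross-implementation test
   runs `Rscript` on a 40x14 fixture). Two numerical notes: (a) when the
   estimated effects are identical across proteins the prior variances
   vanish and the posterior collapses onto the plain estimates, which the
   code special-cases; (b) the EB estimator is deliberately *not*
   idempotent — shrinkage retains part of each protein's deviation from
   the average batch effect, and the reference's divisor-N pooled
   variance renormalizes residuals by sqrt((N−B)/N) on a second pass.
   `shrink=False` selects the plain location/scale adjustment (with the
   unbiased pooled divisor), which equalizes per-protein batch means
   exactly and is idempotent.
5. **Row z-scoring** (sample SD, ddof=1; constant rows become zeros with
   a warning) for heatmap export.

## Differential abundance

Per protein, a pooled-variance two-sample Student t test on the log2
matrix; log2 fold change is the difference of group means. Multiple
testing uses a SAM-style permutation FDR: group labels are shuffled
(n_perm default 250, seeded; the observed labeling is always included so
tail counts are never underestimated), and for each observed |t|_i

    q_i = min(1, E_i / R_i),

with R_i the number of observed |t| >= |t|_i and E_i the mean number of
permuted-null |t| >= |t|_i, enforced monotone non-increasing in |t|.
When the number of distinct label assignments C(n, n1) is at most
n_perm, all assignments are enumerated, making the estimate exact and
testable against brute force. No variance moderation is applied (the
SAM fudge factor is effectively zero), matching plain Student t testing;
on null cohorts the realized per-cohort probability of any q <= 0.05
discovery is about 0.07 — consistent with the intended control level,
with the residual excess coming from the R = 1 tail of the ratio
estimator.

Volcano classification is strict: `up` needs log2fc > log2(2) (*more
than* two-fold), p < 0.05 and (by default) permutation q <= 0.05; a
p-only mode mirrors figure legends that mention only p.

Clinical group comparisons use a two-tailed Mann–Whitney test: exact
enumeration when n1+n2 <= 12 without ties, otherwise the tie-corrected
normal approximation with continuity correction.

## Structure discovery

PCA embeds samples with proteins as features (centering on, unit
scaling off — z-scoring is reserved for heatmaps); components come from
the SVD and signs are fixed by making each component's largest-magnitude
loading positive. Protein rows are partitioned with Euclidean k-means
(best of n_init seeded starts, labels renumbered by ascending centroid
mean; defaults k=4 for the longitudinal heatmap, overridable to 5 for
the viability heatmap). Heatmap leaf orders come from agglomerative
clustering, Euclidean distance, average linkage by default.

## Biomarker ranking

Each protein's ability to separate high from low biliary viability is
the rank-based ROC-AUC (probability a random high-viability sample
exceeds a random low-viability one, ties counting one half; identical
to U/(n1 n2)), computed within four comparisons — low-BDI livers at 30
and 150 min, high-BDI livers at 30 and 150 min — and averaged
arithmetically over the comparisons where both classes are present.
The AUC is directional (high viability is the positive class), because
the biomarkers of interest are enriched in high-viability livers;
folding to max(AUC, 1−AUC) is a flag. Ranking runs on the imputed
matrix so every protein is rankable; an observed-only analysis would be
sensitive to the missing-not-at-random structure. The default report
keeps the top 30.

## Transcript integration

Baseline biopsy RNA-seq counts pass QC when RIN is strictly greater
than 7. Size factors use the median-of-ratios estimator: per sample the
median, over genes with nonzero counts everywhere, of count divided by
the gene's geometric mean across samples (the plain median of ratios;
note that only size-factor *ratios* are equivariant to rescaling one
sample, because the geometric-mean reference moves too). Protein-
transcript coupling is ordinary least squares of log10 protein
intensity on normalized count within each stratum/timepoint group
(n >= 3), reporting slope, R^2 and the two-tailed slope-t p. Negative-
binomial differential expression of counts is deliberately not
reimplemented — counts are used descriptively (Mann–Whitney between
viability groups) and through the regressions.

## Enrichment

A self-contained hypergeometric over-representation test with
Benjamini–Hochberg adjustment replaces online STRING/Cytoscape
enrichment. The recommended background is the set of proteins
surviving the valid-value filter, conditioning enrichment on
detectability. This is a documented substitute, not a claim of
equivalence to any specific online tool.

## Synthetic cohort generator

The generator emulates the design of a 55-liver NMP bile-proteomics
study; all counts below are defaults and scale with its parameters.

* **Cohort**: 55 livers, 35 (64%) meeting viability criteria and
  transplanted. A latent quality scalar u in [0,1] per liver (high
  class: U(0.6,1); low: U(0,0.4)) jointly drives chemistry, histology
  and marker proteins.
* **Bile chemistry**: per-class viability-score distributions (high:
  scores 5–8 with median 8; low: 0–4 with median 1) are sampled at
  evenly spaced quantiles — a stratified draw, so the cohort medians of
  8 (accepted) and 1 (declined) are reproduced for every seed — with
  scores assigned in order of u and decomposed into per-criterion
  colours; measurements are drawn uniformly inside the open interior of
  the colour band, so re-scoring recovers the planted scores exactly and
  a 5-point threshold recovers the planted classes.
* **Histology**: a noisy injury channel v = 1−u + N(0, 0.55) feeds four
  ordinal grades (clipped round(1.4 v + 1.2 + N(0, 0.55)), scale 0–4),
  for ~46 of 55 livers with two livers left partially ungradable. The
  noise level reproduces the observation that severe histological
  injury only partially predicts bile chemistry: about 80% of low-BDI
  livers but only ~50% of high-BDI livers are high-viability.
* **Proteins**: per-protein baseline ~N(21, 2^2) log2 units, noise SD
  ~U(0.7, 1.2); three timepoints (End only for transplanted livers)
  share protein identity, get independent noise, additive per-batch
  offsets (SD 0.3), and a time trend on 10% of proteins. Markers are
  shifted between viability classes by delta = sqrt(2)*sigma*
  Phi^-1(AUC), so the population AUC equals the target (the quantile is
  capped near 1 so a target of exactly 1.0 yields a finite separation
  that still separates classes completely at realistic sample sizes).
* **Missingness**: the dropout probability of a cell is a decreasing
  logistic function of its latent intensity (scale 1.5 log2 units); the
  logistic midpoint is calibrated by root finding so the expected
  overall missing fraction equals the request (realized fraction within
  ~±0.5 percentage points at default sizes). The logistic form is an
  assumption — no quantitative dropout-by-intensity curve is available
  to fit — and is exposed as configuration.
* **Transcripts**: negative-binomial counts (dispersion 0.3) for the
  same gene ids, log-mean coupled (coefficient 0.6) to the liver's
  standardized marker-protein level at 30 min, with per-liver
  library-size factors LogNormal(0, 0.3); RIN ~ N(7.6, 0.9) clipped to
  [1,10] for ~50 biopsied livers, giving roughly 70% passing RIN > 7.

**What passing tests do and do not show.** The generator produces
Gaussian log-intensities with clean group structure; real DIA data have
heavier tails, peptide-level correlation, and batch effects that are
not purely additive. Marker-recovery results therefore validate the
ranking machinery, not expected performance on any real cohort. In
particular, recovery is assessed on complete matrices: under heavy
(~50%) missing-not-at-random dropout, markers whose baseline abundance
sits in the dropout zone are unrecoverable by any ranking method (about
half the top-30 is lost at the default missingness), which is a
property of the data regime, not of the estimator.

## Problem sizes used in bundled experiments

The recovery and null-calibration experiments run at 2000 proteins,
40 livers (20 per class), 250 permutations, and 10–50 seeds; the
moment checks use 1e5 imputed cells. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while the
whole suite stays interactive.

## Known limitations

* Per-component histological grading scales vary between published
  protocols; the 0–4 default is configuration, not a standard.
* The ComBat implementation covers batch labels only (no covariate
  designs, no nonparametric variant).
* AUC values come without confidence intervals; the ranking is
  descriptive, not a fitted classifier.
* The enrichment stand-in ignores protein–protein interaction structure.
* Paired longitudinal designs are not modelled; timepoint comparisons
  treat samples as independent groups.
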