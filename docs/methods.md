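# Methods

`stratomics` implements a genotype-stratified case-control
differential-abundance workflow for plasma proteomics and metabolomics
panels, together with a synthetic-cohort generator that plants known
effects so every stage can be validated against construction.  This note
documents the statistical model, the defaults and why they were chosen,
the numerical conventions, and what the synthetic validation does and does
not demonstrate about real data.

## Study design and model

Samples are grouped into genotype strata (e.g. APOE diplotypes 33, 34, 44,
2x) so that case-control comparisons are made within a genotype.  Within
each stratum, samples are split 50/50 into discovery and replication
halves, stratified by case/control status so the class balance differs by
at most one sample between halves.

Each analyte is tested per half with logistic regression,

    logit P(AD) = b0 + b_age * Age + b_sex * Sex + beta * p,

where `p` is the normalized analyte level; `beta` is reported with its Wald
standard error and a two-sided Wald p-value.  Wald inference was chosen
over the likelihood-ratio test because it matches the default output of
the standard regression packages this kind of analysis is run with.  Sex
enters as a single binary indicator and age in years, untransformed.
Samples with a missing analyte value are dropped casewise, and the number
of samples actually used is recorded per fit.

The two stage estimates are pooled with the inverse-variance-weighted
(IVW) fixed-effect model:

    w_n = 1 / se_n^2
    beta_pooled = sum_n w_n beta_n / sum_n w_n
    se_pooled   = sqrt(1 / sum_n w_n)
    chi2_1      = (beta_pooled / se_pooled)^2,   p_meta = P(X2_1 >= chi2_1)

Benjamini-Hochberg FDR is computed over `p_meta` within each
(stratum x omics-type x model) family — matching per-genotype reporting —
and an analyte is called differentially expressed (DEP/DEM) when

    p_discovery <= 0.05  AND  p_replication <= 0.05  AND  FDR <= 0.05
    AND  sign(beta_discovery) = sign(beta_replication).

FDR applies to the meta p-values only, not separately within the
replication set.  The conjunction makes the rule strongly conservative
under the null: the empirical false-call fraction in the all-null
simulation is far below 1%.

Two sensitivity analyses probe robustness: a joint analysis refits the
logistic model on the pooled stratum (discovery + replication), and a
linear sensitivity model reverses outcome and predictor
(`analyte ~ status + age + sex`).  Agreement is summarized as the Pearson
correlation of effect sizes, the R^2 of the -log10 p-values, and the
fraction of called analytes with matching effect direction.

## Quality control

The six-step aptamer/sample filter operates on the raw (positive,
RFU-like) matrix:

1. low signal: >15% of samples below `buffer_mean + 2*buffer_sd`;
2. calibration: max plate deviation of the calibration factor from the
   plate median > 0.5;
3. replicate noise: median CV > 0.15;
4. distribution: >15% of samples outside `[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`
   of the aptamer's log10 values;
5. sample outliers: a sample with >15% of its values outside the
   per-aptamer fences;
6. shared outliers: a surviving aptamer whose fence violations occur in
   >= 80% of the flagged sample outliers (implemented as `>= 0.80`, a
   conservative literal reading of "approximately 80%", configurable).

Design choices where the procedure is underdetermined: quartiles use
linear interpolation (type 7), the most common default, fixed for
reproducibility; aptamer criteria 1-4 are evaluated on the unfiltered
matrix (so their flag set is order-independent), because the original
ordering relative to sample removal is ambiguous; an analyte flagged by
several criteria is reported under the first that fires; criteria needing
vendor tables (buffer, calibration, CV) are skipped with a logged warning
when the table is absent, since public matrices rarely ship them; missing
values are excluded from every fraction's denominator.

## Normalization

Raw values are log10-transformed.  Batch effects are removed per analyte
by fitting the additive model `value ~ batch` with sum-to-zero coding and
subtracting the batch terms; this preserves the unweighted mean of batch
means and equals limma's `removeBatchEffect` for a single factor (verified
against limma in the test suite).  No covariates are protected in the
batch model.  Datasets are then merged on their common analytes.
Per-dataset z-scoring (divisor n-1) is available behind a flag and is OFF
by default on the primary path; when enabled, effect sizes are on the
per-SD scale and the output records the scale used.  Whether to z-score
before the logistic fit is genuinely open — calling is unaffected (the
logistic p-value is invariant to linear rescaling of the predictor), only
the effect-size units change.

## Quadrant concordance

Pooled effect sizes of the analytes called in either of two strata form a
2D cloud (stratum A on x, stratum B on y).  A center line is fitted by
ordinary least squares of y on x — OLS rather than total least squares
because the procedure is defined as a linear regression; the resulting
line is not rotation-equivariant, which is recorded as a known property
(translations of the cloud do preserve distances).  Each point's signed
perpendicular distance

    d_i = (y_i - slope*x_i - intercept) / sqrt(1 + slope^2)

is computed and sigma is the sample SD of the d_i.  Points with
`|d| <= 1.5 * sigma` (the band multiplier is configurable) in quadrant 1
are `consistent_up`, in quadrant 3 `consistent_down`.  Outside the band,
points are labeled by quadrant, Q1/Q3 split by residual sign: `_top`
means the stratum-B effect is the stronger one.  With Gaussian
perpendicular scatter the expected in-band fraction is
Phi(1.5) - Phi(-1.5) = 86.6%.  Points exactly on an axis take the sign of
their non-zero coordinate (the concordant side); the origin counts as
quadrant 1.  With `sigma = 0`, off-line points fall outside the band by
definition rather than raising an error.

## Enrichment and cell-type specificity

Gene-set enrichment uses the one-sided (greater) Fisher exact test — the
upper hypergeometric tail P(X >= a) — because only enrichment, never
depletion, is of interest here.  The gene universe is the unique gene
symbols of the post-QC analytes of the analyzed stratum; multiple aptamers
of one gene collapse to one universe entry, hit if any aptamer is called.
GO-style collections are filtered to sets with 10-500 in-universe genes;
KEGG-style collections are not size-filtered.  Pathway p-values are
reported raw against a 0.05 cutoff, with a BH column emitted for
information only.  The odds ratio is the plain cross-product ratio
`ad/bc` with no continuity correction (infinite when `bc = 0 < ad`).

Cell-type specificity assigns each gene to the reference cell type with
the largest proportional contribution to its summed mean expression,
provided that contribution is at least 1.5x the second largest
(inclusive); because the row total cancels, this equals the same rule on
raw means.  Ties and zero-total genes stay unassigned.  Fold enrichment
of a DEP set over the background is `log2[(a/|dep|)/(b/|bg|)]` per cell
type, with 0.5 added to both counts when either is zero so the value
stays finite and sign-correct.

## Network growth

A background protein-protein interactome (undirected, unweighted,
self-loop-free) is grown from root nodes — by default the 5 DEP genes
with the highest background degree; the root count is configurable since
no canonical value exists.  Shortest paths are unweighted hop counts
(breadth-first search).  At each step the remaining candidate closest to
any current network node joins, along with its path's connector nodes and
edges.  Tie-breaking is deterministic: lexicographically smallest
candidate symbol, then lexicographically smallest path node-sequence —
reproducibility over arbitrariness.  Candidates in components not
containing a root are reported as unreachable.  Node provenance (root /
dep / connector) is written with the network so external comparisons
(e.g. prize-collecting Steiner approaches) remain possible.

## Synthetic cohort generator

The generator emulates the features the analysis assumes:

- several strata of `n_samples_per_stratum` samples (default 600) at
  `case_fraction` 0.45, approximating a large AD case-control plasma
  study; cases average 5 years older than controls (75 vs 70, SD 8) so
  age adjustment is non-trivial; sex is balanced;
- two collection batches split ~50/50 with an additive `batch_shift` of
  0.3 log10 units;
- log-normal abundances: `log10 x ~ N(baseline + batch + delta*status,
  noise_sd^2)` with baselines Uniform(2.5, 4.5) and `noise_sd` 0.25 log10
  units, a realistic mid-range assay CV;
- planted effects that are shared across strata, specific to one stratum,
  or opposite-signed between the first two strata (fractions 0.10 / 0.05 /
  0.05 by default), with per-SD log-odds `effect_size_logodds` = 0.8;
- optional missing-completely-at-random blanks (metabolomics emulation;
  casewise deletion in the fits covers them — the field's actual
  imputation practice varies and is not modeled);
- annotations matched to the cohort: a mostly-1:1 analyte-to-gene map with
  occasional multi-aptamer genes, gene sets spanning sizes 5-600 plus one
  planted set containing 80% of the shared-effect genes, a 13-cell-type
  nonnegative reference with ~60% dominant-type genes, a connected PPI
  background (random spanning tree plus extra edges) over genes and
  connector nodes, and metabolite super/sub-pathway labels.

The planted coefficient is calibrated so that the asymptotic logistic
slope per standard deviation of the analyte equals the requested
log-odds: for Gaussian class conditionals the induced slope per unit is
`delta/noise_sd^2`, so `delta` solves
`(delta/noise_sd^2) * sqrt(noise_sd^2 + delta^2 p(1-p)) = beta`
(closed form in `synthetic_cohort._calibrated_shift`).  At n=600 per
stratum and beta=0.8 the pooled meta estimates average within 0.1 of
truth with >= 90% CI coverage and >= 95% sign recovery.

A dedicated QC fixture plants at least three violators of each of the six
QC criteria, constructed so each violator trips exactly the criterion it
was planted for (e.g. low-signal aptamers get a buffer threshold at their
20th percentile; shared-outlier aptamers violate their fences in all five
planted sample outliers while helper contamination is rotated so no clean
aptamer reaches the 80% sharing bar).  Running the QC chain on the
fixture must recover the planted flags exactly.

### What the synthetic validation does not show

The generator draws analytes independently (no correlation structure or
co-regulation), plants purely additive batch effects, uses Gaussian log10
noise without heavy tails, and ties effects to status only (no
age-by-analyte confounding).  Passing tests therefore demonstrate the
correctness of the procedures and their calibration under the assumed
model — not robustness to correlated analytes, non-additive batch
distortions, informative missingness, or genotype-specific covariate
structure in real cohorts.

## Problem sizes and numerics

The validation suite uses one-stratum cohorts of 250 samples with 1000
analytes for the concordance and null-calibration checks, and two strata
of 600 samples with 300 analytes for planted-truth quadrant recovery —
sizes at which every quantity of interest is stable across seeds while
the whole suite runs in well under a minute of fitting time.  Logistic
fits use Newton scoring with at most 100 iterations; fits that do not
converge, show non-finite standard errors, or return |beta| > 50
(separation artifacts) are marked unconverged, excluded from pooling, and
never called.  p-values are clipped into (0, 1].  Batch removal is
idempotent to 1e-10.  All seeds flow through `numpy.random.default_rng`;
identical seeds give bitwise-identical cohorts, splits and pipeline
outputs (verified via manifest checksums).
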