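# Methods

This note documents the models, estimators and design choices behind
`sf-somaqc`, and what the synthetic study designs do and do not show.

## The data and its technical structure

An aptamer array run yields a samples × SOMAmers matrix of relative
fluorescence units (RFU).  Each SOMAmer is measured at one of three
dilution fractions (0.20, 0.005, 0.00005); the bin is chosen by target
abundance so that high- and low-abundance proteins land in a similar RFU
range.  Each 96-well plate carries 83 participant wells, one pooled-OA and
one pooled-injury replicate, five plasma calibrators, three plasma QC
wells and three buffer-only blanks.

On the log scale the package models a measured value as a sum of a
per-SOMAmer baseline, biology, and technical terms: a per-well
hybridisation factor, a per-plate intensity factor, a per-(plate, SOMAmer)
calibration factor, an intracellular-contamination component
`u_i · λ_p`, a bimodal processing-state component, confounder effects
(sample age, freeze-thaw count, blood staining), and technical noise.  The
pipeline removes these terms in a fixed order; each stage below states its
estimator exactly.

## Standardisation (linear scale)

* **Hybridisation normalisation.**  For each plate, the reference for
  control *h* is the median over the plate's wells of its RFU; each well's
  factor is the median over controls of (reference / observed) and every
  value in the well is multiplied by it.  By construction the per-well
  median of (reference / RFU) is exactly 1 afterwards, and on purely
  multiplicative data the step is idempotent.  A side effect worth knowing:
  the step re-centres each plate at its median well factor, which then
  becomes part of the plate-level intensity removed by plate scaling.
* **Plate scaling.**  One factor per plate: the median over SOMAmers of
  (calibrator reference / plate calibrator median).  References come from
  the annotation when present, otherwise the across-plate median of plate
  calibrator medians (single-run self-reference).  A single factor per
  plate is used; per-dilution-bin factors would also be estimable but a
  single run does not need them.
* **Median signal normalisation** (implemented, excluded by default).
  Within each dilution bin and sample-role group (study+pooled vs
  calibrator-type wells), each sample is divided by its median ratio to the
  per-SOMAmer cohort median.  Excluded because per-sample total-signal
  differences in this matrix are substantially biological (the
  intracellular component): on synthetic data with that structure planted,
  enabling the step strictly lowers the correlation between the
  standardised values and the generating biological signal, mirroring the
  degradation it causes on replicate %CV and immunoassay concordance.
* **Calibration.**  Per plate and SOMAmer, values are multiplied by
  (reference / plate calibrator median), pinning every plate's calibrator
  median to the reference exactly.
* **Log transform.** Natural log by default (configurable base).

All factors are strictly positive and recorded; re-applying the stored
factors to raw data reproduces the standardised matrix bit-for-bit.

## Repeatability metrics

`%CV` is 100·sd/mean across pooled replicates (sample sd, *n*−1), on
linear standardised RFU (vendor convention; log-scale CV by flag).  The
non-technical R² compares pooled-replicate variance against the variance
of individual study samples on the log scale.  Two printed variants of the
formula circulate for this assay; the package defaults to
`1 − (V_pooled/V_total)²` and also implements `(1 − V_pooled/V_total)²`,
recording the choice in provenance.  Both are monotone decreasing in
V_pooled, and agree at the endpoints.  Note the estimator's limits: with
*k* replicate plates, V_pooled is a *k*−1-df variance estimate, so an R²
threshold at 0.5 only separates classes reliably when the true variance
ratio is far from √0.5 — one reason the study design runs 22 plates, and
why desk-scale 4-plate runs show a visible false-removal rate for this
filter.

Immunoassay concordance is the Pearson correlation of log RFU against log
absolute concentration per analyte, with Fisher-z 95% intervals, skipping
analytes with fewer than 4 overlapping samples.

## Intracellular Protein Score

Weights: `d_p` is the paired Cohen's d_z — mean over pairs of
Δ = log C(unspun) − log C(spun), divided by the sd of Δ (*n*−1) — from 18
spun/unspun aliquot pairs; a pooled-sd variant is available by flag.
SOMAmers with zero-variance differences are excluded rather than capped
(avoids infinite weights) and listed on the model.  The sign convention
(unspun − spun) makes higher IPS mean more intracellular signal.  Weights
are estimated once on the paired subset and frozen; scoring never
re-estimates them.

Scoring is the plain weighted sum over the model's SOMAmers.  Adjustment
is per-SOMAmer OLS on the centred score (intercept included), replacing
each value by residual + mean: it preserves per-SOMAmer means exactly and
zeroes the in-sample covariance with the score to floating-point
precision — consequently *any* linear functional of the adjusted data,
including every principal component score, is exactly uncorrelated with
the IPS.  `covariate_adjust` generalises this to several jointly-fitted
continuous covariates (complete-case, rank-checked).

## Bimodal classification and batch correction

The GMM is a 1-D two-component mixture with distinct variances and free
mixing weight, fitted by EM: initial means at the 25th/75th percentiles of
the PC2 scores (restarts jitter the init; best likelihood of 5 kept, seed
recorded), convergence at log-likelihood change < 1e-8 or 500 iterations.
Assignment is by maximum posterior; exact ties go to the lower-mean
component and are flagged.  The "high" label always belongs to the
larger-mean component, making labels order- and run-stable.

ComBat follows the standard parametric empirical-Bayes procedure exactly:
batch-design least squares with a batch-size-weighted grand mean; pooled
variance with an *n* denominator; per-batch method-of-moments priors
(normal on locations, inverse-gamma on scales); iterative conditional
updates to relative tolerance 1e-4 (the stopping rule mirrors the
reference implementation so iteration counts match); and the usual
standardise/shrink/rescale back-transform.  A single batch is explicitly
an identity.  Correctness is established by elementwise agreement with
Bioconductor `sva::ComBat` (~1e-13 on shared fixtures).  Two properties
worth stating because they are sometimes assumed stronger than they are:
the grand mean is preserved only to second order in the shrinkage
residuals (a few percent of σ at small batch sizes), and under
*gene-constant* batch effects the prior shrinks strongly and residual
standardised mean differences of ~0.1–0.2 remain — identically so in the
reference implementation.  With per-gene-varying effects and adequate
batch sizes both residuals vanish.

"Correct for bimodal status and plate at the same time" is implemented as
two sequential ComBat passes (status, then plate; order configurable), with
a status × plate interaction-batch mode by flag.  Correction applies to
the study + pooled analysis set; assay-control wells are dropped from the
corrected dataset (they are plasma/buffer, not synovial fluid, and the
linear standardised dataset retains them for LOD work).

## PCA and component selection

PCA is SVD on the study+pooled submatrix, centring only by default (the
abundance structure of unscaled log loadings is itself diagnostic;
unit-variance scaling by flag), with a deterministic sign convention (the
largest-magnitude element of each loading vector is positive).  Top-PC
selection takes the smallest k whose cumulative variance fraction reaches
the threshold (default 0.80).  UMAP embedding of the top-k scores is a
thin optional wrapper, excluded from all quantitative contracts.

## Filters

Fixed order, each step seeing the previous step's survivors: control and
non-human reagents; confounder association (per-SOMAmer OLS slope test,
Bonferroni per confounder across SOMAmers, α = 0.05); non-technical R²
below 0.5 in either pooled group; vendor-flagged samples; sub-LOD samples;
total-RFU outliers; PC-space outliers (PCA refit on the survivors, per-PC
|score| > 5 SD over the top PCs covering 80% of variance — the per-PC rule
is chosen over a Mahalanobis radius; a radial mode would be an easy
extension).  Boundary conventions are strict everywhere ("more than 25%",
"beyond 5 SD", "less than 50%").  LOD and total RFU are computed on
standardised linear RFU, confounder/R²/PCA on the log scale.  The lower
LOD is median(blanks) + 4.9 × *unscaled* MAD (the 4.9 multiplier is
calibrated to the raw median absolute deviation; the 1.4826-scaled variant
is available by flag); the upper LOD is a fixed 80,000 RFU ceiling.  Only
study and pooled wells are subject to sample filters.  Re-running the
battery on its own output removes no further samples; the estimate-based
R² step may drift by a reagent or two because its variance denominators
change once bad samples are gone.

## The synthetic study designs

The generator's defaults mirror a large multi-centre study design at desk scale: 22
plates (2112 wells) and 600 SOMAmers standing in for 7596.  One seed feeds
fixed per-effect substreams, so toggling one effect never perturbs
another, and identical seeds give bitwise-identical data.  Key planted
structure, with rationale:

* **Intracellular factor.**  Latent score u_i ~ lognormal(0, 0.4),
  winsorised at exp(0.8) (contamination saturates; keeps linear-scale
  tails physical).  Loadings λ_p grow linearly with the rank of *low*
  dilution-adjusted abundance (max 1.6), so the factor loads on scarce
  proteins and total RFU — dominated by abundant proteins with near-zero
  loadings — stays nearly untouched, matching the observed absence of a
  total-protein effect in real runs.
* **Biology.**  Eight correlated factor modules (geometric 0.9^k variance
  profile, 0.10 per-SOMAmer variance) plus independent residual (sd 0.15).
  The module structure gives the PCA spectrum a realistic shape: the 80%
  threshold is reached within ~40 PCs instead of hundreds, which is what
  keeps the per-PC 5-SD outlier rule's false-positive rate near zero.
  Pooled samples are 6-donor mixtures, so their biological offset is a
  point *inside* the factor subspace (mean donor coordinates, 1/√6 scale);
  an orthogonal pool-specific direction would masquerade as its own
  principal component and flag every pooled well as an outlier.
* **Bimodal artefact.**  30% of proteins affected, ±0.35 log units by
  per-sample status with random per-SOMAmer orientation (mean-preserving);
  status flips between consecutive processing batches with probability
  0.5 and within batches with probability 0.02.  Pooled samples carry one
  fixed status (each pool is processed once and sub-aliquoted), so the
  artefact does not inflate replicate %CV.
* **Technical factors.**  Well factors: a column gradient (amplitude 0.12)
  plus per-well noise (sd 0.24 — hybridisation efficiency genuinely varies
  this much well-to-well).  Plate factors: stratified normal quantiles
  (sd 0.10), randomly permuted — a fixture generator should plant its
  nominal between-plate variance in every run, not a χ²-distributed
  amount.  Calibration effects: sd 0.05 per (plate, SOMAmer).  Calibrator
  wells carry plasma-grade technical noise (sd 0.05), study wells sd 0.2.
* **Planted failures** (counts for the filter battery): 10 sub-LOD samples
  (35% of values collapsed to the blank floor), 5 PC outliers (±1.5 log
  units with a sign-asymmetric pattern that is mean-preserving on the
  linear scale, so they are not simultaneously total-RFU outliers), 3
  total-RFU outliers (×4), 2 vendor-flagged; 12 control reagents (4 hyb
  controls + 8 other control types/non-human), 50 confounder-associated
  SOMAmers (35 sample-age at 0.05 log/yr, 15 freeze-thaw at 0.15
  log/cycle), and 30 low-R² reagents modelled as *dead and
  handling-sensitive*: no biological response, doubled noise, and 1.5×
  extra noise in pooled wells (pooled aliquots are thawed per plate,
  study samples once) — the structural V_pooled > V_total margin a
  variance-ratio threshold needs at 22 replicates.

What the passing tests do **not** show about real data: the generator has
no aptamer cross-reactivity, no disease effects, no missingness beyond
planted metadata gaps, Gaussian log-noise, and exactly multiplicative
technical factors.  Conclusions about estimator calibration and planted
effect recovery transfer; absolute %CV and variance-share levels are
design choices, not predictions.

## Numerical choices and degenerate inputs

Medians everywhere in standardisation (robustness to single outlying
wells); OLS via QR; PCA via LAPACK SVD with the sign convention above; EM
with a likelihood floor against zero-density points; a constant-PC2 input
yields a flagged non-converged assignment with posteriors 0.5 rather than
an error.  Strictly positive values are required before log transforms
(the offending cell is named).  ADAT I/O emits floats with
shortest-round-trip `repr`, making write→read lossless.

## Known limitations

Single-run scope (no inter-run calibration); parametric ComBat only; the
confounder filter is simple OLS per confounder (no joint model); IPS
weights require a paired spun/unspun subset and inherit its sampling
noise (rank correlation with the true loadings ≈ 0.9 at 18 pairs);
UMAP output is visualisation-only.  The R² filter's discriminating power
is bounded by the number of replicate plates, as quantified above.
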