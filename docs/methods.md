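# Methods

This package re-implements, as a tested pipeline, a flow-cytometry analysis
for relapse risk in childhood B-cell acute lymphoblastic leukaemia (B-ALL):
per-patient marker expression is summarised as percentile curves, class
differences are scored with a Fisher's-Ratio matrix, and new patients are
classified by a distance-based probability measure against per-class control
curves.  Because the clinical cohort this kind of analysis is run on is not
publicly available, the pipeline is driven by a synthetic multi-tube cohort
generator whose defaults encode the study conditions (56 patients, 13
relapses, ~20-marker panel split over tubes sharing backbone markers).

## Synthetic cohort model

Each patient is a hierarchical mixture model on the logicle display scale
(decades):

* A cell is a B-lymphoblast with probability `b_fraction` (default 0.85,
  per-patient logit jitter sd 0.30), otherwise a non-B cell.
* Per marker and cell population, fluorescence is a two-component Gaussian
  location–scale mixture: a negative component (autofluorescence, ~0.9
  decades, sd 0.30) and a positive component (~2.2–3.0 decades, sd
  0.30–0.40).  Mixing weights are marker- and population-specific (CD19 is
  strongly bimodal: positive in ~98.5% of B cells and ~2% of non-B cells, so
  the automated gate always has two modes to find).
* Patient-level random effects: the positive/negative component locations
  jitter between patients with sd 0.15/0.10 decades and the mixing weights
  with logit sd 0.35.  These random effects are what give the Fisher's
  Ratio a positive within-class variance to divide by; their scales were
  chosen once as a realistic between-patient immunophenotype spread and are
  not tuned.
* Relapse effect: for relapse-class patients, a configured marker's
  *positive* component is shifted by `delta` decades for fraction `f` of
  positive cells (default: CD38, delta = −1, f = 1).  A shift of the whole
  distribution would be removed exactly by the per-patient quantile
  normalisation below; shifting the positive component relative to the
  negative one changes the distribution's shape, which is the only kind of
  signal that can survive per-patient normalisation.  A consequence is that
  the planted difference expresses itself from roughly the 25th percentile
  up — the lowest percentiles sit in the negative component, which the
  normalisation pins at its 5th-percentile anchor.
* Tubes: each tube draws its events independently from the same patient
  model, so nearest-neighbour merging across tubes is statistically
  consistent.  Marker values are conditionally independent given the cell
  population, so the backbone markers (CD19/CD45/CD34) carry exactly the
  information the merge needs.
* Covariates: age (log-normal, median 3.75 y), sex, blast % (Beta),
  karyotype category (hyperdiploid/normal/hypodiploid with ~20% missing),
  translocation flags and time to relapse (relapsers only) at the rates of a
  typical B-ALL cohort.  Binary covariates can be *linked* to a marker: the
  indicator thresholds a latent Gaussian correlated (coefficient `rho`) with
  the patient's standardised positive-component location for that marker,
  including any class effect.  Defaults: hyperdiploidy rho −0.5, female
  +0.4, t(12;21) +0.4, all to CD38 — giving the inverse CD38–hyperdiploidy
  and higher-in-females patterns the association stage is meant to recover.
* Randomness: one integer seed; per-patient/per-tube/per-purpose substreams
  are spawned by counter keys, so regeneration is bit-identical and partial
  regeneration (e.g. a fresh complete event matrix for one patient) is
  reproducible.

What the generator does *not* emulate: instrument artefacts (time drift,
margin events, debris, doublets — the pipeline starts from pre-cleaned
events), batch effects beyond what quantile normalisation absorbs,
cross-marker correlation within a cell population, and non-B lineages.
Tests passing on this generator therefore show the pipeline implements its
contracts and recovers effects of the planted form; they cannot show that
real relapse biology is detectable at any particular effect size.

## Preprocessing

1. **Compensation** — `true = observed @ S⁻¹` with the spillover matrix `S`
   carried in each FCS file.
2. **Logicle transform** — Parks–Moore biexponential with w = 0.75,
   t = 262,144, m = 4.5, a = 0 (defaults).  The inverse has closed form; the
   forward transform inverts it by safeguarded bisection (64 iterations,
   round trip accurate to ≤1e-6 relative over [−0.1 t, t]).  Output is in
   display decades.
3. **Tube merging** — the tube with the most markers is the reference (ties:
   first in file order); every other tube donates its tube-specific markers
   to each reference cell from that cell's nearest neighbour (k = 1,
   Euclidean) in backbone-marker space, ties broken to the lowest donor
   index.  Imputation is star-shaped (each donor tube imputed independently
   onto the reference), avoiding order dependence.
4. **Normalisation** — per marker, `x' = (x − q05) / (q95 − q05)` with the
   patient's own 5th/95th percentiles, clipped to [0, 1] by default (config
   switch).  A state flag forbids double application, since re-applying
   would recompute quantiles on already-scaled data.  Degenerate markers
   (q05 = q95) are an error naming the marker.
5. **CD19 gating** — after normalisation, a Gaussian KDE (Silverman
   bandwidth, 512-point grid) on CD19; the threshold is the deepest density
   minimum between the two largest modes; cells above it are retained.
   Unimodal densities require an explicit fallback threshold.  The KDE has
   no random component, so the gate is deterministic.
6. **Subsampling** — uniform without replacement to a fixed count, seeded
   per patient.  Run-config default is 3,000 events (the gate retains
   roughly 85% of 5,000 generated events, so 5,000 would be unattainable);
   100,000 mirrors a full-scale acquisition and remains configurable.  A
   patient with fewer gated cells than the target is an error, not a
   with-replacement resample.

Markers not present for every patient are dropped to the cohort's common
panel (at least 15 by default) before analysis.

## Expression representations

* **Summaries** — per marker: median (MFI), mean, sample (n−1) sd.
* **Percentile vectors** — empirical quantiles at a 5,10,…,95 grid (P = 19,
  linear interpolation between order statistics).  Rows are nondecreasing
  by construction and live on [0, 1] after clipping.
* **Generalized-logistic fit** of the cumulative curve
  `F(I) = K / (1 + A e^{−αI})^{1/γ}` with K = 1.  `A` is not free: the curve
  is anchored through (I at the 1st percentile, 0.01), which determines `A`
  in closed form given (α, γ).  α and γ are estimated by bounded nonlinear
  least squares in log-parameters from a 3×3 grid of restarts (α started
  from 4× the slope at the median, γ from 1).  γ = 1 recovers the logistic
  curve; γ → 0 approaches the Gompertz curve (the fitter reproduces a
  Gompertz target within 0.02 everywhere).  Non-convergence is flagged in
  the result object, never raised.  Fits are descriptive output only — the
  fitted parameters are compared between classes but not used as
  classification features.

## Fisher's-Ratio model and classifier

With classes R (relapse) and N (non-relapse), the feature (marker j,
percentile k) is scored as

    FR_jk = (μ_Rjk − μ_Njk)² / (σ²_Rjk + σ²_Njk),

with μ the across-patient class **median** of the feature (mean by config)
and σ the within-class sample sd.  Features with FR > 0.5 are selected; if
none passes, the single best feature is used so every cross-validation fold
can build a classifier.  σ estimation needs at least two patients per class
in every training set; fold draws violating this are redrawn.

Classification uses per-feature class-membership probabilities with a shared
denominator (so they sum to 1 exactly), orientation convention
`proximity` — membership probability decreases with distance to that class's
reference — with the opposite (`as-printed`) orientation available.  Three
distance geometries are implemented:

* `feature` (default): per selected feature, the absolute difference between
  the patient's percentile value and each class's **median-curve** value.
* `curve`: the same comparison per marker, Euclidean over the marker's
  selected percentile levels.
* `scaled`: distances between the σ-scaled points R̄ = μ_R/σ_R,
  N̄ = μ_N/σ_N and P̄ = v/((σ_R+σ_N)/2).

The scaled geometry is kept for completeness but is not the default because
it is only coherent when a feature's class scales are comparable: P̄ is
scaled by the *mean* of the class sds while each reference point is scaled
by its *own* sd, so when σ_R ≈ 2σ_N the decision boundary lands on the N
class, and when clipping saturates a feature in one class (σ → 0) that
class's reference point diverges.  Measured on planted-effect cohorts the
scaled default gave LOOCV accuracy ≈ 0.27 versus ≈ 0.99 for the median-curve
geometry, which is also the geometry the method's own illustration draws
(distances from a patient's cumulative curve to the two class median
curves).

The patient's relapse probability is the mean of per-feature probabilities;
the hard label uses threshold 0.5 with ties assigned to N (no prior
weighting — the symmetric choice).

## Validation harness

* **Cross-validation**: LOOCV and stratified K-fold (K capped by the smaller
  class), repeated; selection and fitting strictly inside training folds;
  out-of-fold predictions pooled per repeat; metrics reported mean ± sd
  across repeats.  LOOCV folds are deterministic, so with a deterministic
  classifier its across-repeat sd is 0 by construction.
* **Metrics**: accuracy, sensitivity, specificity, PPV, NPV (NaN when a
  denominator is empty) and trapezoidal ROC AUC with R as positive class.
* **Feature frequency**: over 100 random stratified 75:25 splits, the
  fraction of classifiers (filtered by a test-accuracy threshold,
  inclusive) that used each marker.
* **Random-Forest comparison**: per run, a 75:25 split, a 50-tree forest
  with bootstrap OOB scoring, and marker-level permutation importance on
  the held-out quarter.  Importance permutes a marker's whole percentile
  block jointly: the 19 levels of a marker are so correlated that permuting
  single columns (then summing) measures exactly zero at this problem size —
  the remaining levels stand in for the shuffled one.  The per-column + sum
  mode is retained as an option.
* **Class comparisons**: two-sample t-tests (equal-variance by default,
  Welch by config) on per-patient median/mean/sd and fitted α/γ, flagged at
  p < 0.05 with no multiplicity correction (a Benjamini–Hochberg switch
  exists but is off, mirroring common practice in exploratory cytometry
  reports).

Under a true null this classifier does **not** degenerate to majority-class
guessing: its relapse probabilities straddle 0.5 broadly (LOOCV on a small
minority class even inverts them slightly, because removing a relapse
patient shifts the relapse median away from that patient), so null LOOCV
accuracy sits near 0.55–0.65 rather than at the 0.77 majority rate.  This is
a property of symmetric distance rules with a fixed threshold, not an
implementation defect; the corresponding calibration check in the acceptance
suite documents the gap and is expected to fail.

## Association stage

Selected percentiles of a marker (default CD38 at P15/P50/P85) are joined to
the encoded clinical table (relapse = 1, male = 1, one-hot karyotype,
alteration flags, time to relapse missing for non-relapsers) and correlated
pairwise by Pearson's r with p-values from the exact t-transform, over
pairwise complete cases (≥4 pairs; constants yield missing cells; nothing is
imputed).  The report holds full r/p/n matrices; the display matrix shows r
below and p above the diagonal.  Group contrasts (e.g. CD38 P50 by sex) use
two-sample t-tests; a single-patient group is an error unless a Welch
fallback is requested.

## Problem sizes and determinism

Default analysis conditions: 56 patients (13 relapse), 3 tubes × 5,000
events, 18 markers, subsample 3,000, percentile grid P = 19.  The simulation
studies in the test suite use these conditions for planted-effect and null
calibration checks (20 and 5–10 seeds respectively) and reduced cohorts
(6–16 patients, hundreds of events) for contract tests.  All randomness in
generation, fold assignment, splits and forests flows from explicit integer
seeds; the end-to-end run writes byte-identical outputs when repeated under
the same config.

## Known limitations

* The per-marker mixture family is an assumption; real marker distributions
  are not characterised by the source study and may be heavier-tailed or
  multi-modal within the positive population.
* Effects planted as positive-component shifts are the only class signal the
  generator can produce; subpopulation-presence effects (a distinct rare
  cluster) are out of scope, and the percentile representation would be
  partially blind to them anyway.
* The scaled control-point geometry is retained for literal reproduction but
  is known to be fragile (above); results obtained with it should not be
  compared against the default geometry.
* Whether to gate before or after normalisation is not fully settled in the
  methodology this follows; this implementation normalises first, then
  gates, and the fidelity checks are defined for that order.
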