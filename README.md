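# cytorelapse

Relapse-risk analysis of childhood B-cell acute lymphoblastic leukaemia
(B-ALL) from diagnostic flow cytometry.

About one in five children with B-ALL relapses after first-line therapy, and
the flow-cytometry data collected at diagnosis — per-cell fluorescence of
~20 immunophenotypic markers such as CD19, CD10 or CD38 — is used to
identify the leukaemic clone but not, today, as a prognostic signal.  This
package implements a pipeline that asks whether marker *expression level*
separates relapsing from non-relapsing patients at diagnosis:

1. **Preprocessing** — per-tube FCS 3.0 files are compensated with their
   spillover matrix, transformed to the logicle display scale
   (w = 0.75, t = 262144, m = 4.5, a = 0), merged across tubes by
   nearest-neighbour imputation on shared backbone markers, normalised per
   marker to `x' = (x − q05)/(q95 − q05)`, gated to CD19⁺ B cells by a
   density threshold, and subsampled to a fixed event count.
2. **Percentile curves** — each patient × marker becomes the vector
   `x_ij ∈ R^P` of empirical percentiles (5th–95th, P = 19), plus MFI-style
   summaries and an anchored generalized-logistic fit of the cumulative
   curve `F(I) = K/(1 + Ae^{−αI})^{1/γ}`.
3. **Fisher's-Ratio selection and classification** — features (marker j,
   percentile k) are scored by

       FR_jk = (μ_Rjk − μ_Njk)² / (σ²_Rjk + σ²_Njk)

   with class medians μ and within-class sds σ; features with FR > 0.5 form
   a classifier that converts a new patient's distances to the two class
   median curves into relapse/non-relapse probabilities (mean over selected
   features, threshold 0.5).
4. **Validation** — repeated LOOCV/K-fold with in-fold feature selection,
   accuracy/sensitivity/specificity/PPV/NPV/AUC, marker usage frequency
   over 100 random 75:25 splits, and a Random-Forest comparison (50 trees,
   OOB error, marker-level permutation importance).
5. **Associations** — Pearson correlations of CD38 percentiles (P15/P50/P85)
   with clinical and cytogenetic covariates, and group contrasts by sex.

Real cohorts of this kind are not publicly deposited, so the package ships a
first-class synthetic cohort generator (`cytorelapse.synthetic`) that
emulates multi-tube acquisition with spillover, bimodal marker expression,
patient-level heterogeneity, a plantable relapse signature (default: the
CD38 positive component shifted one decade down in relapse patients) and
covariates correlated with marker expression.  Every stage of the pipeline
is tested against it.  See `docs/methods.md` for the model and all design
choices.

## Worked example

```python
from cytorelapse import pipeline, synthetic, validate
from cytorelapse.fisher import fisher_matrix

# a 56-patient cohort, 13 relapse, CD38 planted one decade down in relapse
cohort = synthetic.generate_cohort(n_patients=56, prevalence=13/56,
                                   events_per_tube=5000, seed=1)
pms = pipeline.direct_percentiles(cohort, subsample_n=3000)

model = fisher_matrix(pms)                     # class statistics + selection
print(sorted(model.marker_level_fr().items(), key=lambda kv: -kv[1])[:3])
report = validate.cross_validate(pms, scheme="loocv", repeats=1, seed=1)
print(report.mean[["accuracy", "auc"]])
```

prints (seed 1):

```
[('CD38', np.float64(8.814146719985516)), ('CD20', np.float64(0.2308220755512663)), ('CD15', np.float64(0.21165745722480347))]
accuracy    1.0
auc         1.0
dtype: float64
```

CD38's marker-level Fisher's Ratio (its FR averaged over the 19 percentile
levels) is ~40× the next marker's, i.e. the planted one-decade shift
dominates every other source of between-class difference, and leave-one-out
cross-validation separates the two classes completely at this effect size.
With no planted effect the same pipeline selects no marker above threshold
and its label-permutation AUC is ~0.5.

The same analysis as a sequence of narrative steps lives under `analysis/`
(01 simulate → 02 preprocess from the FCS files → 03 expression summaries →
04 Fisher model → 05 validation → 06 clinical associations), each writing
its tables to `results/`.  An end-to-end run from one config is also
available as a CLI:

```bash
cytorelapse run --config analysis/config.yaml --out out/
```

which writes percentile tables, the serialised model, a scheme × metric
performance table, feature-frequency and Random-Forest reports, and the
correlation matrix, bit-identically for a fixed seed.

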