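# Methods

This note documents the models, defaults and design choices behind
`phenorisk`, and what the synthetic-data tests do and do not establish
about real cohort data.

## Synthetic cohort model

The generator emulates a prospective cohort of diabetes-free adults with
six planted risk phenotypes (VLR, LRLB, LRHB, HRHBP, HRBF, HRIR).

* **Mixture structure.** Cluster membership is multinomial with mixing
  weights equal to the published cluster sizes over the cohort total
  (e.g. VLR 1891/7317 in the Swedish-like cohort). Two parameter sets are
  packaged: `sdpp` (Swedish-like, with 2-h post-load glucose) and `msc`
  (Mexican-like, fasting only).
* **Features.** Within a cluster, continuous features (fasting glucose
  mmol/L, fasting insulin μU/mL, 2-h glucose mmol/L, BMI kg/m², SBP/DBP
  mmHg, baseline age years) are independent Gaussians at the published
  per-cluster means/SDs, truncated at physiologic floors (glucose ≥ 3.6
  mmol/L, insulin ≥ 1 μU/mL, BMI ≥ 15, SBP ≥ 80, DBP ≥ 50) so HOMA
  indices stay computable. Only marginal moments are published, so
  independence is an assumption; an equicorrelation knob
  (`CohortConfig.numeric_correlation`) exists for robustness checks but
  defaults to 0. Categorical features (sex, family history, education) are
  multinomial at the published per-cluster proportions (category counts
  over cluster size).
* **HOMA indices are derived, not drawn.** HOMA-B and HOMA-IR are computed
  downstream from the drawn glucose/insulin, preserving the deterministic
  dependency the real data have.
* **Survival.** Event times are exponential with the cluster's published
  incidence rate (per 1000 person-years, converted to per person-year) as
  a constant hazard, administratively censored at 23 years (the cohort's
  average follow-up). A Weibull shape parameter is exposed for
  robustness tests; when shape ≠ 1 the scale is set to keep the mean event
  time equal to the exponential case.
* **Longitudinal visits.** Follow-up visits at 10 and 20 years re-draw each
  clustering feature as baseline + N(0, drift_sd), floor-truncated; a
  participant whose event precedes a visit enters the absorbing `T2D`
  state. The default drift SD is 0.6 × the feature's within-cluster SD —
  a one-time choice representing combined measurement error and biological
  drift over a decade, large enough that cross-visit reassignment,
  regression to low risk and progression to diabetes all occur.
* **Covariates** (smoking, comorbidity, physical activity, general health)
  are drawn independently of cluster with fixed realistic marginals; they
  are confounder slots, not clustering inputs, and no confounding is
  planted by default.

What passing tests on these cohorts show: the pipeline can recover a known
mixed-data cluster structure, its planted hazards, and the published
qualitative orderings under the stated generative assumptions. What they do
not show: robustness to within-cluster correlation, non-Gaussian marginals,
informative censoring, recruitment bias (the original Swedish cohort
oversampled family history), attrition, or confounded covariates — none of
which are modeled by default.

## Preprocessing

* **HOMA.** The updated homeostasis-model (HOMA2) calculator is a licensed
  program without a published closed form, so the default is the classical
  closed-form equations HOMA-IR = G·I/22.5 and HOMA-B = 20·I/(G − 3.5)
  (G in mmol/L, I in μU/mL). These differ in scale from HOMA2 output but
  preserve the relative ordering that drives the cluster geometry. Users
  with HOMA2 calculator output can inject it via `method="precomputed"`.
  Glucose ≤ 3.5 makes HOMA-B undefined; such rows get NaN and fall to the
  missing-data exclusion.
* **Exclusions** run in a fixed order — age window (Mexican cohort: 30–60
  years) → complete case on the clustering variables → diabetes at the
  baseline examination (fasting ≥ 7.0 mmol/L or 2-h ≥ 11.0) — and are
  logged per rule.
* **Standardization and trimming.** Continuous clustering variables are
  z-scored; rows with |z| ≥ 5 in any feature are removed as extreme
  outliers. Parameters are fitted once on all baseline analysis rows,
  *then* trimming is applied, and the frozen parameters are reused for
  follow-up visits and bootstrap replicates — refitting per visit would
  change the cluster geometry over time and make "remained in a high-risk
  cluster" ill-defined. The boundary is exclusive (|z| exactly 5 is
  removed). Categorical variables are encoded as dense integer codes over
  sorted levels.
* **Glycemic classes.** IFG is fasting glucose in [5.6, 6.9] mmol/L (ADA)
  or [6.1, 6.9] (WHO); IGT is 2-h glucose in [7.8, 11.0) — the upper bound
  is open because 2-h ≥ 11.0 is diabetes, avoiding class overlap. Missing
  2-h glucose (fasting-only cohorts) never yields IGT. "Prediabetes" as a
  binary marker means any of IFG/IGT/both under the chosen criteria.

## k-prototypes

The dissimilarity is squared Euclidean on the standardized numeric block
plus γ times the number of categorical mismatches. Defaults and numerical
choices:

* γ defaults to Huang's heuristic, 0.5 × mean numeric SD (≈ 0.5 on
  standardized data; on the trimmed matrix the heavy right tail of HOMA-B
  pulls it slightly below). γ is reported in all outputs.
* Initialization draws k distinct data rows (seeded); a frequency-weighted
  categorical initialization is available. `n_init=20` restarts by
  default, best final cost kept.
* Updates: within-cluster mean / mode; mode ties break to the lowest
  category code, assignment ties to the lowest cluster index — both
  deterministic across platforms.
* Convergence: label stability or relative cost change < 1e-6, up to 100
  iterations. The internal cost sequence is asserted non-increasing on
  every fit, and the final cost is re-verified against the returned
  prototypes/labels.
* An emptied cluster is reseeded from the row currently farthest from its
  assigned prototype; fitted models never contain empty clusters.
* Correctness anchors: exhaustive-enumeration equivalence on small
  instances (n ≤ 10), and exact agreement with Lloyd's k-means when there
  are no categorical features (γ irrelevant, q = 0).

## Cluster validity

* **Gap statistic.** The cited construction covers numeric data only; the
  mixed-data extension here draws reference numeric features uniformly
  over each observed column range and reference categorical features from
  the observed marginal frequencies. `W` is the total k-prototypes cost.
  `s_k` uses the usual √(1 + 1/B) correction; `n_refs=50` by default
  (reduced in examples/tests for speed); chosen k is the smallest
  satisfying the one-SE rule, else the largest k in range.
* **Bootstrap stability.** Resample rows with replacement, refit, and for
  each reference cluster take the maximum Jaccard between its member set
  and any bootstrap cluster's member set, both restricted to the unique
  resampled row ids (the clusterboot convention). The bootstrap-to-
  reference matching rule is not uniquely determined by the field's usage;
  max-Jaccard per reference cluster is the standard convention and ours.
  Stability threshold 0.75 on the per-cluster mean (B=1000 by default;
  B=200 in the acceptance checks).
* **Cluster matching.** One-to-one correspondence between two models by
  Hungarian assignment, maximizing total member-set Jaccard (same rows) or
  minimizing summed prototype distance on the standardized scale
  (different cohorts). Fitted clusters are *named* by matching their
  prototypes to reference prototypes built from the published per-
  phenotype means; the names are descriptive conveniences, not claims.

## Survival analysis

Attained age is the time axis: participants enter the risk set at baseline
age (left truncation) and exit at their event or censoring age, which
controls for age far more tightly than a follow-up-time axis with age as a
covariate. Models are stratified by 5-year birth-year bands (secular
trends), use Efron tie handling (age-scale data are heavily tied), and
dummy-code the exposure against the LRHB reference. Estimation is
delegated to `lifelines.CoxPHFitter`; the contract (truncation, strata,
ties, reference, Wald CIs) is pinned by tests, including recovery of a
planted HR = 2 within the model's own CI. Incidence-rate CIs use the
log-normal approximation `rate · exp(±1.96/√D)` — it reproduces the
published intervals exactly — with exact Poisson intervals behind a flag;
zero cases yield rate 0 with flagged-undefined bounds. Kaplan–Meier curves
use the left-truncation-aware product-limit estimator.

## Evaluation

* For a dichotomous marker the ROC has one interior point, so
  AUC = (sens + spec)/2 exactly; this identity is consistent with all
  published AUC values and is asserted to 1e-12. Wilson CIs for
  proportions (the original CI method is unstated), Hanley–McNeil for AUC.
* Transition analysis is complete-case over participants observed at every
  visit; `T2D` is validated absorbing and the summary is anchored at
  baseline risk group (remained / crossed to the other risk group /
  progressed to diabetes at the final visit).
* Agreement (κ, AC1) is computed pairwise between visits (baseline↔10y,
  baseline↔20y, 10y↔20y) among participants diabetes-free at both visits
  of the pair — the pooling across visits is otherwise ambiguous, and
  including the absorbing state would inflate agreement. κ's chance term
  is the sum of marginal products; AC1's is (1/(q−1)) Σ π_k(1−π_k) with
  π_k the mean marginal, which keeps it stable under the skewed marginals
  that make κ paradoxical.

## Pipeline

`run_full_analysis` derives every stage seed deterministically from the
global seed (SeedSequence, kept below 2³¹), so a config + seed pair is
byte-reproducible, and writes a manifest with a config hash, stage seeds,
row counts and timings. Clusters are called high-risk when their incidence
rate exceeds the overall rate (ties flagged); with the packaged parameters
this splits the six phenotypes 3/3. When the fitted k differs from the six
packaged phenotypes the clusters keep generic names and the Cox reference
falls back to the largest cluster.

## Problem sizes

Defaults in examples, tests and the acceptance script are sized for a
single CPU: cluster-number selection and stability on cohorts of
2,000–5,000 participants with `n_refs=10` and B=100–200; planted
hazard-ratio recovery on 3 × 10,000 participants; planted incidence-rate
recovery on 20,000. These are the package's own reduced analysis sizes;
the full-scale settings (B=1000, n_refs=50, n≈7,300) are the library
defaults and run in minutes.

## Known limitations

* HOMA1 closed forms stand in for the HOMA2 computer model (scale shift;
  ordering preserved).
* The generator's independence and constant-hazard assumptions are
  simplifications; see the synthetic-cohort section for what that limits.
* No imputation (complete-case only), no competing-risks modelling of
  death, no formal proportional-hazards test (the original analysis
  assessed PH visually), and no uMAP/heatmap visual validation.
* The original analysis's exact γ, initialization and restart count are
  not public; the defaults here are documented substitutes, not claims
  about the original run.
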