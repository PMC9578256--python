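# phenorisk

Data-driven risk phenotyping of diabetes-free adults: mixed-data cluster
analysis of common type 2 diabetes risk factors, cluster-validity
assessment, and survival-based risk stratification, with a synthetic cohort
generator that makes the whole analysis testable without access to
restricted cohort data.

## The scientific problem

Prediabetes (impaired fasting glucose and/or impaired glucose tolerance) is
the standard tool for flagging adults at high risk of type 2 diabetes, but
it stratifies on glucose alone and misses most incident cases. An
alternative is to partition the diabetes-free population into phenotypes
using the joint variability of routine risk factors — fasting glucose and
insulin, the derived homeostasis-model indices HOMA-B (β-cell function) and
HOMA-IR (insulin resistance), BMI, systolic and diastolic blood pressure,
sex, family history of diabetes, and education — and ask whether the
resulting clusters stratify long-term diabetes risk better than prediabetes
does. Six recurrent phenotypes emerge in both a Swedish and a Mexican
cohort: very low-risk (**VLR**), low-risk low β-cell function (**LRLB**),
low-risk high β-cell function (**LRHB**), high-risk high blood pressure
(**HRHBP**), high-risk β-cell failure (**HRBF**), and high-risk
insulin-resistant (**HRIR**).

`phenorisk` is aimed at epidemiologists and biostatisticians who want to
reproduce, stress-test, or extend this kind of analysis.

## Methods at the core

* **k-prototypes clustering** (written from scratch): partition mixed data
  by minimizing
  `Σ_i [ ‖x_i − μ_{c(i)}‖² + γ · #{j : z_ij ≠ m_{c(i),j}} ]`,
  where `μ_c` are numeric cluster means, `m_c` categorical modes, and γ
  weights category mismatches (default: Huang's heuristic, half the mean
  numeric SD, i.e. 0.5 on standardized data). Alternating
  assignment/update, best of `n_init` seeded restarts.
* **Gap statistic** for the number of clusters, extended to mixed data:
  `Gap(k) = E*[log W_k] − log W_k` with reference data uniform over each
  numeric range and multinomial on observed categorical marginals; choose
  the smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}`.
* **Bootstrap cluster stability**: per-cluster mean Jaccard similarity
  `|A∩B|/|A∪B|` between reference clusters and refits on bootstrap
  resamples; mean > 0.75 counts as stable.
* **Survival validation**: person-years and incidence rates with log-normal
  CIs (`rate · exp(±1.96/√D)`); Cox proportional hazards with **age as the
  time scale** (left truncation at baseline age), stratified by 5-year
  birth cohorts, Efron ties; left-truncation-aware Kaplan–Meier curves.
* **Clinical utility**: sensitivity/specificity (Wilson CIs) and the
  two-point AUC `(sens + spec)/2` (Hanley–McNeil CI) of dichotomous
  markers; state-transition tables with an absorbing diabetes state; and
  chance-corrected agreement of repeated assignment (Cohen's κ and Gwet's
  AC1).
* **Synthetic cohorts**: a six-component mixture over the clustering
  variables whose means/SDs, category proportions, mixing weights and
  per-cluster hazards are the published per-phenotype values, plus
  longitudinal visits with measurement drift.

## Worked example

```python
import phenorisk as pr

cfg = pr.RunConfig(n_participants=4000, seed=5, n_init=8, stability_B=20)
res = pr.run_full_analysis(cfg)
print(res["accuracy"][["marker", "sensitivity", "specificity", "auc"]].round(3))
```

prints

```
            marker  sensitivity  specificity   auc
high_risk_clusters        0.631        0.730 0.681
   ADA_prediabetes        0.165        0.930 0.548
   WHO_prediabetes        0.051        0.974 0.512
```

— on this synthetic cohort the three clusters whose incidence exceeds the
overall rate capture 63% of incident cases at 73% specificity, while the
glucose-threshold prediabetes definitions are highly specific but miss
83–95% of cases; the two-point AUC summarizes the same trade-off. The run
also returns per-cluster incidence rates split into three low- and three
high-risk phenotypes, Cox hazard ratios against the LRHB reference
(recovering the ordering VLR < LRLB < 1 < HRHBP < HRBF < HRIR), bootstrap
stability, 20-year transition tables and between-visit agreement (κ ≈ 0.8).

The `examples/` directory has one short narrative script per capability:
cohort generation, clustering and phenotype naming, validity (gap +
bootstrap), survival stratification, clinical utility, and the full
pipeline with its artifact directory.

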