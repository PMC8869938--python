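# endorisk

Risk-stratification engines and survival evaluation for early-stage
(FIGO I–II) endometrial cancer cohorts.

About 15% of early-stage endometrial cancers recur, and three competing
clinical tools try to say which ones: the clinicopathological
**ESMO-ESGO-ESTRO 2016** four-group classifier, the molecular **ProMisE**
surrogate of the TCGA subtypes (POLE / MMRd / NSMP / p53abn), and the
molecular-integrated **ESGO-ESTRO-ESP 2020** four-group classifier.  A
persistent weakness of all three is the overlap of their intermediate
prognostic tiers.  `endorisk` implements all three rule engines plus a
three-tier refinement that reallocates *CTNNB1* exon-3 mutated patients
from the 2020 intermediate tiers to the high-risk group and merges the
remaining intermediates — together with the statistical machinery needed
to compare such classifiers on censored survival data, and a calibrated
synthetic-cohort generator so the whole pipeline is testable without
patient-level data.

It is written for biostatisticians and translational researchers who hold
a cohort CSV (one row per patient: clinicopathological variables,
binary molecular marker calls, RFS/OS follow-up in months) and want
reproducible classifier comparisons.

## What it computes

For a cohort with survival endpoint (T, δ) and a classifier assigning each
patient an ordinal risk tier g ∈ {1, …, k}:

- **Kaplan–Meier** product-limit curves per tier, with Greenwood variance
  and log–log 95% bands; the headline per-tier statistic is the 5-year
  rate Ŝ(60 months).
- **Cox proportional hazards** with the tier as a single ordinal covariate
  (Efron or Breslow ties): h(t|g) = h₀(t)·exp(β·g), reported as the
  hazard ratio exp(β) per one-step increase in severity.
- **Concordance index** of the tier score under Harrell's
  permissible-pair rules for censored data, with the raw
  concordant/discordant/tied pair counts exposed (so the strict
  Goodman–Kruskal gamma (C−D)/(C+D) is available from the same counts);
  c = 0.5 is uninformative, 1 is perfect ranking.
- **k-group log-rank** tests, univariate Cox screens with the standard
  clinical covariate codings, and reclassification (Sankey) matrices
  between schemes.
- **Predictive mean matching** imputation of non-evaluable (`NE`)
  molecular calls, taking the modal donated value over many independently
  seeded runs.

The synthetic generator draws risk tiers from configurable proportions,
gives each tier an exponential relapse hazard λ_g = −ln(S₆₀)/60 calibrated
to its 5-year rate, censors by uniform accrual over 144 months with an
administrative cutoff (75-month median follow-up), and assembles feature
bundles that the corresponding classifier provably maps back to the
anchored tier.

## Worked example

```python
import endorisk as er

cfg = er.SimConfig(n_patients=293, group_scheme="proposal", seed=7)
cohort = er.generate(cfg)                 # synthetic cohort with NE gaps
cohort, log = er.pmm_mode_impute(
    cohort,
    er.ImputationConfig(
        n_runs=100,
        target_columns=("lvsi", "mmr_status", "p53_ihc", "ctnnb1_exon3"),
        seed=7,
    ),
)
print(f"imputed {len(log.chosen)} non-evaluable cells")
ev = er.evaluate_proposal(cohort, endpoint="rfs")
print(ev.summary())
```

prints

```
imputed 35 non-evaluable cells
Risk stratification evaluation — scheme: c2020, endpoint: RFS
n = 293 (293 classified)
==============================================================
      group          n (%)    5-yr rate (%)    95% CI   events
--------------------------------------------------------------
              low 138 (47.1%)          87.0 (78.4-92.3)     15
     intermediate  60 (20.5%)          69.5 (54.0-80.6)     21
high_intermediate  52 (17.7%)          66.5 (49.1-79.2)     17
             high  43 (14.7%)          41.5 (24.8-57.5)     25
--------------------------------------------------------------
Ordinal Cox (efron ties): HR per step 1.91 (95% CI 1.57-2.32), p = 1.3e-10
  coding: ordinal low=1, intermediate=2, high_intermediate=3, high=4
c-index = 0.69
log-rank chi2 = 59.37 (df=3), p = 8e-13

Risk stratification evaluation — scheme: proposal, endpoint: RFS
n = 293 (293 classified)
=========================================================
   group        n (%)    5-yr rate (%)    95% CI   events
---------------------------------------------------------
         low 138 (47.1%)          87.0 (78.4-92.3)     15
intermediate  89 (30.4%)          76.0 (63.5-84.7)     24
        high  66 (22.5%)          40.3 (26.8-53.4)     39
---------------------------------------------------------
Ordinal Cox (efron ties): HR per step 3.02 (95% CI 2.25-4.06), p = 2e-13
  coding: ordinal low=1, intermediate=2, high=3
c-index = 0.72
log-rank chi2 = 72.48 (df=2), p = 1.8e-16

c-index delta (proposal - 2020): +0.031
```

Reading it: the cohort was simulated under the three-tier proposal's own
generating model (mutated intermediates share the high-tier hazard), so
collapsing to three tiers both sharpens the per-step hazard ratio
(3.02 vs 1.91) and raises the concordance index by 0.031 — the 293-patient
analogue of the improvement the refinement is designed to deliver.  The
low tiers of the two reports are identical by construction; the proposal's
high tier absorbs the 23 mutated intermediate patients.

The same pipeline is available from the shell:

```bash
endorisk simulate --seed 42 cohort.csv
endorisk impute --runs 1000 --seed 1 cohort.csv complete.csv
endorisk classify --scheme proposal complete.csv labelled.csv
endorisk survival --scheme 2020 --endpoint rfs --out report.json complete.csv
endorisk compare --schemes 2016,promise,2020,proposal --endpoint rfs complete.csv report.json
```

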