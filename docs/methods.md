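# Methods

## Scope and data model

`endorisk` operates on early-stage (FIGO I–II) endometrial-cancer cohorts:
one row per patient with clinicopathological variables (age, endometrioid
vs non-endometrioid histology, differentiation grade G1–G3, myometrial
invasion none / <50% / ≥50%, FIGO stage IA/IB/II, binary LVSI), binary
molecular calls (POLE exonuclease-domain variant token, MMR and p53 IHC,
*CTNNB1* exon-3 status, plus ER/PR/ECAD/HER2/ARID1A/PTEN/L1CAM), and two
disease-specific endpoints in months: relapse-free survival (surgery to
first recurrence or death from disease) and overall survival (surgery to
death from disease; other deaths are censored upstream of this schema).
"Five-year" always means 60 months.  Non-evaluable calls are an explicit
`NE` state so that imputation is a visible transformation, never silent
NaN handling.  Tumour size, though often collected, feeds no rule or
statistic here and is deliberately absent from the schema.

Two schema invariants are enforced at validation rather than silently
repaired: stage/depth consistency (IA ⇔ no or inner-half invasion,
IB ⇔ outer-half) and RFS ≤ OS.

## Rule engines

The four classifiers are pure, total decision functions over the
categorical vocabulary; each input combination yields exactly one label or
one *explicit* unclassifiable outcome (e.g. missing LVSI on a branch that
needs it).  Precedence in the molecular subtype assignment is
POLE → MMRd → p53abn → NSMP; a pathogenic POLE variant dominates every
other call.  POLE pathogenicity is membership of a configurable whitelist
(shipped as JSON package data with the 11 accepted hotspot exonuclease-domain
variants); any other EDM alteration is deliberately ignored for
classification.  Two documented simplifications in the 2020 engine: the
cohort-style binary LVSI maps onto the guideline's substantial-LVSI
branch, and all non-endometrioid histologies are treated uniformly.  In
the three-tier refinement, a *CTNNB1* status still `NE` after imputation
maps to wild-type — the conservative default given the low mutation
prevalence (≈8%).

## Survival statistics

* **Kaplan–Meier.** Product-limit estimation is delegated to `lifelines`
  (censorings tied with an event time leave the risk set after the events,
  the standard convention); Greenwood variance is accumulated from the
  event table, and the 95% bands are the log–log ("exponential Greenwood")
  intervals, which respect [0, 1].  Reading a curve past its last observed
  time returns the last step with an explicit extrapolation warning.
* **Cox proportional hazards.** `statsmodels` `PHReg` is the fitting
  engine, with Efron tie handling by default and Breslow selectable.
  A risk scheme enters as a single ordinal covariate scored 1, 2, … in
  severity order (empty tiers are skipped so the score stays contiguous;
  the realised map is recorded in the fit).  ProMisE severity is scored in
  its conventional listing order POLE=1, MMRd=2, NSMP=3, p53abn=4 — an
  order that is *not* monotone in observed survival, which is precisely
  why that classifier tends to show a weak single HR and a near-0.5
  c-index.  A constant covariate or an event-free sample is a refused fit;
  monotone likelihood (perfect separation, singular Hessian) returns a
  result flagged `converged=False` rather than silent numbers.
* **Concordance.** The censoring-aware c-index is implemented in-package
  because the pair counts themselves are part of the contract: a pair is
  permissible iff the patient with the smaller observed time had an event
  (tied times: iff exactly one is an event, the event patient counting as
  shorter-lived); concordant iff the shorter-lived patient carries the
  strictly higher score; score ties count one half.  Evaluation is an
  exact chunked O(n²) enumeration, cross-checked in the tests against both
  a brute-force oracle and `lifelines`.  The strict Goodman–Kruskal gamma
  (C−D)/(C+D) is derivable from the exposed counts.  Because a rule-based
  classifier's only output is its tier, the per-scheme c-index is computed
  on the ordinal tier score.
* **Log-rank.** The k-group test (`lifelines`), df = k−1, is the default
  curve-comparison statistic.
* **Univariate screens** use the standard clinical codings (age >60 vs
  ≤60, high vs low grade, invasion yes/no, ordinal FIGO stage, marker
  positive vs negative, *CTNNB1* mutated vs not), complete-case per
  covariate, with optional subgroup restriction — in particular the merged
  2020 intermediate ∪ high-intermediate subset used for the biomarker
  screen that motivates the three-tier refinement.

α = 0.05 throughout; display rounding is one decimal for percentages and
two for hazard ratios and c-indexes.

## Imputation

Predictive mean matching, re-implemented: each target is regressed on the
predictor design (intercept, standardized age, one-hot clinicopathological
categories; predictor `NE` forms its own indicator level so no row is
dropped) over complete cases, one indicator regression per observed
category level; coefficients are perturbed by a normal draw scaled by a
scaled-inverse-χ² residual-variance draw; each missing case donates the
observed value of one of the k = 5 nearest complete-case predictions
(k configurable), chosen uniformly.  Donation guarantees imputed values
are members of the observed category set.  The headline entry point
repeats this over n_runs = 1000 independently seeded runs (seeds spawned
from one master seed) and keeps the per-cell modal donated value, with
ties broken by the fixed schema category order and every vote logged.
Degenerate predictor designs fall back to an empirical donor draw, logged.
The predictor set default (all clinicopathological columns) is a
documented choice; no multiple-imputation pooling (Rubin's rules) is
offered because the pipeline collapses to a single modal completion by
design.

## Synthetic cohort generator

The generator's defaults encode the published cohort conditions: n = 293;
tier proportions and 5-year RFS rates per scheme (2016: 50.0/14.3/17.4/18.1%
with rates 93.2/76.9/77.5/50.4%; ProMisE: 1.7/23.2/63.5/11.6% with
100/74.7/87.3/52.8%; 2020: 49.5/20.5/17.1/13.0% with 93.9/79.5/72.2/41.5%;
three-tier proposal: 145/88/60 of 293 with 93.9/79.1/42.7%); feature
marginals (endometrioid 88.4%, low grade 80.2%, stage IA 69.3%, LVSI+
18%, and the printed biomarker positivity rates); and per-column `NE`
probabilities from the printed non-evaluable counts (the MMR/p53 shares
are unprinted; a nominal 2% is used).  The proposal's tier sizes derive
from the published 2020 distribution (low 145, high 38, merged
intermediates 110) with a 20% mutation rate among merged intermediates,
i.e. 22 patients reallocated to the high tier.

Model choices, each the minimal faithful option given that only 5-year
rates are printed:

* **Event times** are tier-conditional exponentials with
  λ_g = −ln(S₆₀)/60 per month, so the model's true S(60) equals the
  configured rate exactly.  A single rate parameter is all the printed
  evidence supports; richer shapes can be explored through the config's
  rates but no Weibull default is pretended.
* **Censoring** is uniform accrual over 144 months (a 12-year inclusion
  window) with an administrative cutoff 147 months after the first
  accrual, i.e. C ~ Uniform[3, 147]: median follow-up 75 months, matching
  the published figure in expectation.  Censoring is independent of event
  times.
* **OS** is RFS plus an exponential post-relapse survival (median 24
  months by default): only relapsing patients can die of disease, which is
  what a disease-specific endpoint implies.  The 24-month median is a
  clinically plausible choice consistent with the printed relapse (43) and
  disease-death (26) counts over the follow-up; it is exposed in the
  config.
* **Joint feature structure** is under-determined by printed marginals.
  The declared dependencies are minimal: histology and grade are linked to
  the molecular subtype (aberrant-p53 tumours skew non-endometrioid and
  high-grade), and *CTNNB1* mutation is concentrated in the 2020
  intermediate tiers (20% there, 0.6% elsewhere, ≈7.8% overall) — the
  published composition of the three-tier high group (22 of 60 from the
  merged intermediates) is not reproducible with a flat mutation rate.
  All other features are conditionally independent.
* In **group-anchored mode**, each patient's feature bundle is sampled —
  with marginal-product weights — from the full enumeration of categorical
  combinations that the scheme's own engine maps to the anchored tier, so
  classification round-trips are exact by construction.  In **marginal
  mode** features come first and labels are derived, which is the mode to
  use when the classifier itself is under test.

What the generator does *not* emulate: patient-level covariate
correlations beyond those declared, treatment effects, competing risks,
non-administrative (dropout) censoring, and any within-tier prognostic
heterogeneity (exponential tiers are internally homogeneous).  Passing
recovery tests therefore demonstrates that the statistical machinery is
correct and well calibrated under the stated generating model — not that
the classifiers would achieve the same discrimination on a real cohort.

## Recovery studies and problem sizes

The packaged studies (`endorisk.studies`) use replicate seeds spawned from
one master seed via `numpy.random.SeedSequence`:

* pooled KM tier-rate recovery: 200 replicates per tier at the published
  tier sizes (145 low / 100 intermediate / 48 high per replicate),
  pooled into one product-limit estimate read at 60 months;
* *CTNNB1* hazard-ratio recovery: 500 merged-intermediate subcohorts of
  110 patients (20% mutated), wild-type hazard calibrated to the 79.1%
  tier rate, summarised as exp(mean log-HR) over converged fits;
* proposal-vs-2020 comparison: 100 proposal-anchored cohorts of 293,
  scored by the share of replicates with a non-negative c-index delta.

These sizes keep every study's Monte-Carlo error comfortably below the
tolerances they are judged against while remaining desk-scale.

## Known limitations

* The 2020 engine covers the stage I–II domain only; stage III–IV branches
  of the guideline are out of scope, as is focal-vs-substantial LVSI.
* The c-index is computed on the ordinal tier score; a Cox linear
  predictor would rank identically but could tie differently under other
  codings.
* PMM for categorical targets (per-level indicator regressions with
  nearest-prediction donation) is one reasonable categorical variant, not
  the only one; the mode-over-runs aggregation makes the pipeline robust
  to that choice.
* The censoring model is a declared approximation: real accrual is rarely
  uniform and real follow-up rarely purely administrative.
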