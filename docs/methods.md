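# Methods

## The model

`pactcost` implements a cost-consequence analysis of an early, parent-mediated
communication intervention for preschool autistic children, compared with
treatment as usual in a two-arm design (74 intervention, 69 control
children). Costs are presented alongside — not collapsed into — outcome
evidence, so no cost-effectiveness ratios or QALYs are computed.

Per-child resource-use quantities over a 13-month trial window (service
events or hours) are costed as

    cost(child, category) = Σ_items quantity × unit price (euros, 2020)

with two hour-denominated exceptions: parental time off work is valued at the
national average wage (human capital approach) and informal-care hours at the
market price of a formal caregiver (proxy good approach). Items with a pooled
mean occurrence of ≤ 0.5 events per child are excluded before costing.
Incremental costs (intervention minus control arm means) are aggregated under
three nested perspectives — healthcare service, broader service (adding
education/childcare and social care) and societal (adding the two family
categories) — and decomposed in a waterfall whose final cumulative bar equals
the societal incremental exactly. Family out-of-pocket spending is tracked as
a ninth category outside every built-in perspective; it enters only the
dedicated sensitivity comparison.

### 6-year extrapolation

Long-term resource-use data do not exist, so 13-month costs are projected
under fixed yearly-cost assumptions:

* delivery costs appear only in year 1 (which spans the 13-month delivery
  window; the ≈1-month overhang is ignored rather than prorated);
* education/childcare uses the nursery-derived yearly cost in years 1–2; from
  year 3 all children are assumed to be in primary school, and former nursery
  time is recosted as school time. The school recosting is expressed as
  (school item, units per year) and priced through the unit-cost table, so it
  scales coherently when education unit costs are varied in sensitivity
  analysis;
* every other category repeats its annualized yearly cost each year.

Annualization multiplies 13-month costs by 12/13 (configurable; set 1.0 to
treat trial-window costs as yearly rates — published 6-year totals do not
disambiguate which convention their authors used). Discounting applies
1/(1+r)^(t−1) at r = 3.5%/year with the first modelled year undiscounted, the
usual health-technology-assessment convention; an end-of-year variant is
available because published totals again cannot distinguish the two. Both
choices were fixed a priori as the package's defaults.

### Uncertainty

Mean-cost differences are bootstrapped non-parametrically: children are
resampled with replacement within each arm independently (the child is the
unit of independence; item-level resampling would break within-child cost
correlation), the incremental is recomputed per replicate, and percentile
intervals are reported. Defaults: 1,000 replicates, 95% level. Percentile
rather than BCa intervals were chosen for transparency; with n ≈ 70 per arm
the difference is small relative to the skewness of cost data. Bootstrap is
applied at 13 months, where per-child data exist; 6-year totals are
deterministic transforms of the 13-month means, so their sampling
uncertainty is the transformed 13-month uncertainty.

### Sensitivity analyses

1. **Unit-cost scaling** — unit costs of one category group at a time are
   multiplied by 1 + δ, δ ∈ {±0.2, ±0.3, ±0.5}; all downstream quantities are
   recomputed. Because every stage is linear in prices, scaling *all*
   categories by λ scales every incremental exactly by λ (this homogeneity is
   a test invariant).
2. **Hours taper** — parental productivity-loss and informal-care hours fall
   by 20% from year 3 onward (children aged 6+), years 1–2 staying at trial
   level. The taper is applied to cohort-mean yearly cost streams, not to
   individual children, since the model is mean-based.
3. **Out-of-pocket substitution** — the intervention arm's mean out-of-pocket
   spend (1,696 €) is compared with an external Irish usual-care estimate
   (9,599 €, sum of living costs, care and assistance, education, healthcare,
   travel, training/support and an autism assistance dog). The two means come
   from different studies and are compared as-is after 2020-price inflation;
   no statistical harmonisation is attempted.

Scenario transforms never mutate the base model; identity scenarios (δ = 0,
reduction = 0) reproduce base results bit-exactly.

## Synthetic cohorts and calibration

The trial's microdata are not deposited, so analyses run on synthetic
cohorts. Quantities are zero-inflated gamma: a child uses an item with
probability 1 − p₀, and conditional use is Gamma(shape = dispersion,
mean = μ). The gamma was chosen because service-use and cost data are
nonnegative and right-skewed; the default shape of 1 (exponential) encodes
high skew when no dispersion information exists. Intervention delivery is a
deterministic per-child item (quantity 1 in the intervention arm, 0 in
control): it is a fixed programme cost, not a stochastic service. Each arm
draws from an independent random stream derived from one seed, so resizing
one arm never perturbs the other.

`calibrate_to_means` rescales item means so the *expected* per-child cost per
(arm, category) equals user-supplied targets exactly, splitting a category
target across items in proportion to their prior expected costs. The shipped
England fixture is calibrated to the published arm-level aggregates
(healthcare totals 7,651 vs 1,723 €; broader-service incremental 4,510 €;
societal totals 95,689 vs 99,308 €; delivery difference 6,198 €). The
category-level split inside those aggregates, the unit-cost values, and the
Ireland/Italy/Spain price-level multipliers (1.06, 0.92, 0.88) are
illustrative: the source material does not print them. The
`expected=True` cohort variant makes every item deterministic, giving a
zero-noise cohort whose arm means equal the calibration targets to machine
precision — used to push the published aggregates through the full pipeline.

What the synthetic data do **not** emulate: correlation between items within
a child (no covariance information exists), child-level covariates and age
structure, non-stationarity of service use within the 13-month window, and
any treatment-effect mechanism — arm differences are encoded directly in the
calibrated means. Passing tests therefore demonstrate the correctness of the
costing/projection arithmetic and the distributional plumbing, not the
clinical or economic validity of the underlying trial estimates.

## Numerical and design notes

* All computation is in euros at 2020 prices; non-euro inputs must be
  pre-converted (a combined conversion/inflation multiplier on the unit-cost
  table serves this purpose).
* The item filter is strictly greater-than (mean > 0.5), making the default
  threshold a true boundary; ties drop.
* A category missing from an arm summary is treated as zero with a logged
  warning rather than an error, so partial analyses (e.g. out-of-pocket only)
  run without fully populated summaries.
* Community health-and-social services are split across the healthcare
  (`community_health_social`) and broader (`social_care`) perspectives by
  item-level category mapping, since published tables do not separate them;
  delivery cost sits inside the healthcare perspective (consistent with a
  published healthcare difference of 5,928 € that is *smaller* than the
  6,198 € delivery difference — other health costs partially offset it).
* Bootstrap CIs with fewer than 100 replicates are suppressed (`None`) rather
  than reported from an unstable quantile estimate.
* Monetary values are rounded to whole euros in human-readable tables and
  kept at full precision in JSON exports; every number in a table is also
  present in the machine-readable manifest.

## Problem sizes

Default analyses use the trial-sized cohort (143 children × 9 items) and
1,000 bootstrap replicates. Calibration-recovery checks use 50,000 children
per arm; the bootstrap-versus-enumeration check uses a 2+2-child toy with
10,000 replicates, where the exact resampling distribution (16 equiprobable
pairs) is enumerable.

## Known limitations

* The 6-year totals depend on the illustrative category split and school
  recosting, so they reproduce the *qualitative* published pattern (service
  costs stay positive, societal costs turn strongly negative through informal
  care) rather than the printed 6-year euro values, whose component inputs
  are not public.
* Extrapolation assumes fixed yearly costs; no symptom-trajectory or
  state-transition modelling is attempted.
* Statistical testing of cost differences is out of scope (no test statistics
  are published to reproduce).
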