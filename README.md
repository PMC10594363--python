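# pactcost

Cost-consequence analysis of the PACT early-autism intervention (a 12-session
parent-mediated video-feedback programme for preschool autistic children),
for health economists and policy analysts who want to reproduce, adapt or
stress-test trial-based cost comparisons across countries and time horizons.

## What it computes

For a two-arm cohort (intervention + treatment-as-usual vs treatment-as-usual
alone; 74 vs 69 children by default) the package:

1. **Costs resource use** — per-child service quantities over the 13-month
   trial window are multiplied by country-specific 2020 euro unit costs.
   Parental time off work is valued at the national average wage (human
   capital approach); unpaid care hours at the market price of a formal
   caregiver (proxy good approach). Items used on average ≤ 0.5 times per
   child are dropped before costing.
2. **Aggregates by perspective** — the incremental cost
   Δ = mean cost(intervention) − mean cost(control) is reported under the
   *healthcare service* perspective (intervention delivery, speech and
   language therapy, community and hospital services), the *broader service*
   perspective (+ education/childcare and social care) and the *societal*
   perspective (+ parental productivity losses and informal care), with a
   waterfall decomposition of the societal total.
3. **Extrapolates to 6 years** — delivery costs are confined to year 1,
   nursery costs to years 1–2 (recosted as primary-school time thereafter),
   other categories repeat their annualized yearly cost; future years are
   discounted at 3.5% (`1/(1+r)^(t−1)`, first year undiscounted).
4. **Quantifies uncertainty** — non-parametric bootstrap resampling children
   within arms, with percentile confidence intervals.
5. **Runs deterministic sensitivity analyses** — ±20/30/50% unit-cost
   scaling per category group; a 20% taper of parental hours from year 3;
   and a comparison of family out-of-pocket spending against an external
   Irish usual-care estimate.

Because the trial's microdata are not public, `pactcost.datasets` ships a
synthetic cohort generator (zero-inflated gamma quantities) with a
calibration mode that reproduces published arm-level category means in
expectation.

## Worked example

```python
from pactcost import datasets

# England fixture, zero-noise expected-value cohort
model = datasets.country_model("england", expected=True)
results = model.fit(n_boot=0)
print(results.summary())
```

prints (abridged):

```
Incremental costs (intervention minus control)
       perspective   horizon  incremental
healthcare_service 13 months        5,928
   broader_service 13 months        4,510
          societal 13 months       -3,619
healthcare_service   6 years        4,823
   broader_service   6 years       -2,013
          societal   6 years      -43,396
```

At 13 months the intervention is more expensive from the health system's
point of view (+5,928 € per child) but already cheaper for society as a whole
(−3,619 €), because intervention-arm families provide less informal care.
Over 6 years the informal-care saving compounds and the societal incremental
grows to −43,396 € per child: the intervention pays for itself when family
impacts are counted. `expected=True` uses the calibrated expectation for each
child; drop it (and pass a `seed`) for sampled cohorts, bootstrap CIs via
`fit(n_boot=1000, seed=...)`, and Monte-Carlo variation around these figures.

The same analysis is available from the shell:

```bash
pactcost report --country england --seed 1 --out run1/
pactcost sensitivity --scenario sa3
```

## Layout

| module | contents |
| --- | --- |
| `pactcost.model` | `CostConsequenceModel` / `CostConsequenceResults` |
| `pactcost.cohort` | synthetic cohort generation, calibration, CSV I/O |
| `pactcost.costing` | unit-cost tables, perspectives, incrementals, waterfalls |
| `pactcost.extrapolation` | yearly schedules, discounting, 6-year projection |
| `pactcost.uncertainty` | non-parametric bootstrap |
| `pactcost.sensitivity` | the three deterministic sensitivity analyses |
| `pactcost.datasets` | illustrative four-country fixtures |
| `pactcost.report` / `pactcost.cli` | pipeline runner and command line |

See `docs/methods.md` for the model's assumptions, defaults and limitations.
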