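# tdabc-cea

Cost-utility analysis of **venous stenting vs conservative care (compression
± anticoagulation)** for post-thrombotic leg ulcers, built on **time-driven
activity-based costing (TDABC)**.

Chronic venous leg ulcers after deep-vein thrombosis are managed either
conservatively (compression therapy, monthly outpatient wound care, partly
paid out-of-pocket by patients) or by endovascular stenting of the iliac
outflow obstruction. This package implements the full economic comparison
between the two strategies for analysts and health-economics researchers:

- **`tdabc`** — prices a care pathway by its process map: each step consumes
  minutes of a resource priced at its *capacity cost rate* (EUR/minute),
  plus goods/technology costs and patient-borne costs; rolls steps up into
  per-phase breakdowns, episode costs split by payer, expected cost under a
  re-intervention risk, and reimbursement gaps against DRG/outpatient
  tariffs.
- **`meta_props`** — random-effects pooling of single-arm proportions
  (ulcers healed, ulcers recurred): Freeman–Tukey double-arcsine transform
  (variance `1/(4n+2)`), DerSimonian–Laird `τ²`, Miller harmonic-mean
  back-transform, normal 95% CIs (validated against R `metafor` to 1e-10).
- **`markov`** — three-state Markov cohort model (*active* → *healed* →
  *recurred*) with monthly cycles over 36 months and 3%/year discounting.
  Healing is a tunnel transition at the strategy's mean healing time;
  recurrence is a constant hazard calibrated to the cumulative recurrence
  proportion; recurred ulcers are re-managed conservatively.
- **`cea`** — the incremental cost-utility ratio
  `ICUR = (Cost_A − Cost_B) / (QALY_A − QALY_B)` with dominance labelling,
  ±20% one-way sensitivity (tornado) tables, and a 1000-draw probabilistic
  sensitivity analysis (beta for utilities/proportions, gamma for
  costs/times, SD = 20% of baseline) summarised as a cost-effectiveness
  acceptability curve.
- **`value_report`** — radar-chart value summary on 0–100 axes (reciprocal
  cost ratios anchored to the cheapest strategy; outcome rates as percent).
- **`synthetic`** — generates every input: fixture activity logs whose
  noiseless roll-up reproduces the published cost tables to the cent, noisy
  per-patient variants (unit-mean lognormal), and heterogeneous study pools
  for the meta-analysis.

## Worked example

```python
from tdabc_cea import (roll_up, fixture_stenting_log, fixture_stenting_rates,
                       expected_cost_with_reintervention, run_cea)
from tdabc_cea.synthetic import STENTING_PHASES
from tdabc_cea import config as cfgmod

bd = roll_up(fixture_stenting_log(), fixture_stenting_rates(), STENTING_PHASES)
print(round(bd.totals["total"], 2))    # 5081.99  (EUR per stenting episode)
print(bd.totals["minutes"])            # 2983.0   (minutes of the care cycle)
print(expected_cost_with_reintervention(bd.totals["total"], 0.03))  # 5234.45

res = run_cea(cfgmod.base_case(), "hospital")
print(round(res.qaly_stenting, 3), round(res.qaly_soc, 3))  # 2.672 2.502
print(round(res.cost_stenting), round(res.cost_soc))        # 8806 6822
print(round(res.icur))                                      # 11638
```

The roll-up says one stenting episode consumes 2983 minutes of staffed care
and EUR 5081.99, rising to EUR 5234 once the 3% re-intervention risk is
priced in. Over 36 months the model credits stenting with 0.17 extra QALYs
at EUR 1984 extra hospital cost, i.e. roughly EUR 11.6k per QALY gained —
cost-effective against the common EUR 25k–40k willingness-to-pay range.

The same analyses are scriptable from the shell:

```bash
tdabc-cea icer --perspective societal
tdabc-cea tornado --out tornado.csv
tdabc-cea psa --n 1000 --seed 42 --out-dir psa/
tdabc-cea simulate --what logs --seed 7 --n 50 --out synthetic/
```

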