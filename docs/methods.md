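# Methods

## Costing engine (TDABC)

A care pathway is a list of steps, each holding minutes of one resource,
direct goods/services/technology cost, and any patient-borne cost. Personnel
cost per step is `minutes × capacity cost rate` (EUR/minute of the role's
available capacity); steps performed at only a fraction of visits carry a
`frequency` multiplier applied to minutes and both cost components. Roll-ups
keep all sums unrounded internally and round half-up to the cent only at
reporting; percent shares are whole percents of the unrounded totals, and a
*block* share (e.g. "operative phases") is the sum of the rounded per-phase
percents, the convention used in published TDABC tables.

The fixture tables store sub-cent internals. Published cost tables round
every cell independently of their unrounded internals, so the printed phase
rows, phase totals and grand totals are mutually inconsistent by a cent in
several places; the fixtures carry third-decimal digits chosen so that every
printed cell *and* every printed total is reproduced under half-up rounding.
One consequence: the 3-month conservative-care episode totals EUR 1891.81
unrounded (printed row arithmetic gives 1891.80); both round to the printed
EUR 1892.

An expected re-intervention repeats the full procedure cost, so the expected
episode cost under re-intervention risk `p` is `base × (1 + p)`.

## Proportion meta-analysis

Single-arm healing/recurrence proportions are pooled on the Freeman–Tukey
double-arcsine scale, `t = ½[asin√(x/(n+1)) + asin√((x+1)/(n+1))]` with
variance `1/(4n+2)`: the transform stabilises the binomial variance and
needs no continuity correction at 0 or n events, so boundary studies are
retained. Between-study variance uses the DerSimonian–Laird moment
estimator truncated at zero; `I² = max(0, (Q − (k−1))/Q)`. The pooled
transformed mean is inverted with Miller's closed form at the harmonic mean
of the study sizes (alternative inversion conventions move estimates by
under 1% at these sizes). Confidence intervals use normal quantiles on the
transformed scale (no Knapp–Hartung). A single study is returned as its own
proportion with `τ² = I² = 0`. The implementation reproduces R `metafor`
(`escalc(measure="PFT")` + `rma(method="DL")` + `transf.ipft.hm`) to 1e-10
on a fixed 4-study table frozen in the test suite.

The pooled base-case inputs of the decision model (healing 81%/61%,
recurrence 5%/10%) enter through configuration, not through a live
meta-analysis: the underlying per-study counts are not part of this
package's data, so the pooling machinery is exercised on synthetic pools.

## Markov cohort model

Three health states — *active ulcer*, *healed ulcer*, *recurred ulcer* —
with monthly cycles over a 36-month horizon. The cohort starts fully
active.

- **Healing**: a tunnel transition moves fraction `p_healed` of the initial
  cohort from active to healed at the mean healing time `t_heal` (2 months
  stenting, 3 months conservative). Fractional mean times are honoured by
  splitting the flow across the two bracketing cycles with weights chosen
  so the mean is exact; this keeps the ±20% one-way analysis of the healing
  time (2.4 / 3.6 months) and continuous PSA draws well-defined, which is
  why sampled healing times are not rounded to whole cycles (they are
  floored at 1 month, the cycle length). A `constant_hazard` alternative
  (per-cycle hazard reaching cumulative `p_healed` by `t_heal`, continuing
  thereafter) is config-switchable.
- **Recurrence**: healed ulcers recur with a constant per-cycle probability
  calibrated numerically (Brent root-finding) so cumulative healed→recurred
  flow over the horizon equals `p_recur` of the initial cohort (5%
  stenting, 10% conservative).
- **Recurred ulcers** are re-managed conservatively: only the
  conservative-care healing fraction (61%) of recurrences ever re-heals,
  with a constant per-cycle probability whose mean dwell equals the
  conservative healing time (3 months); the remainder stays recurred. The
  recurred state is internally split into healable/chronic sub-states that
  share the recurred utility and monthly cost and are reported as one
  state. This calibration of the (openly under-specified) transition
  structure was selected because it tracks the reference outcome means —
  QALYs 2.6724/2.5019 vs the reported 2.679/2.498 and all four cost means
  within 1% — where simpler readings (all recurrences re-heal, or none) miss
  the QALY gap by an order of magnitude more.

**Accounting.** QALYs accrue as annual utility weights (healed 1.00, active
0.73, recurred 0.64) divided by 12 per cycle, on start-of-cycle occupancy.
Costs per cycle: the procedure cost (EUR 5234, stenting only, re-intervention
included) at cycle 0 undiscounted; the first outpatient visit (EUR 243.86)
at cycle 1 in the conservative arm only — the stenting admission already
contains the first contact, a reading confirmed by the reference one-way
row for that parameter, which is non-zero only if a single arm carries it;
the monthly management cost (hospital EUR 406.11 / societal EUR 444.83) on
active + recurred occupancy in both arms (after stenting, patients continue
compression therapy until healing, a conservative assumption); and the
healing-phase cost (EUR 127.95 / 313.45) on each healing event, including
re-healing. Both accumulators discount at the compound monthly equivalent
`(1.03)^{1/12} − 1`; the simple `0.03/12` alternative (config-switchable)
differs by <0.02% over the horizon. No half-cycle correction is applied.
The societal perspective adds patient out-of-pocket costs to the hospital
ones; productivity losses are out of scope.

## Cost-utility analysis

`ICUR = ΔCost / ΔQALY`, with labels *dominant* (cheaper, more effective),
*dominated* (dearer, less effective) and *undefined* at ΔQALY = 0.

**One-way sensitivity** re-runs the full model at 80% / 120% of one
parameter at a time (utilities and proportions capped at 1.0); dominance at
a limit is reported as its label and the variation column as "CEA result
change". Because the conservative healing proportion and time also govern
re-management of recurrences, their rows propagate into both arms.

**PSA** draws each parameter from a method-of-moments distribution with
SD = 20% of baseline — beta for utilities and proportions, gamma for costs
and healing times — using one seeded generator in declared parameter order,
so runs are bit-reproducible. The healed-state utility of 1.0 has no
feasible beta with positive SD; it is held at baseline with a warning
(consistent with the one-way cap at 1.0). The acceptability curve is the
share of draws with non-negative incremental net monetary benefit
`λ·ΔQALY − ΔCost` per willingness-to-pay `λ`; it is monotone in `λ` in all
seeded runs exercised by the tests (monotonicity is not guaranteed in
general when draws with ΔQALY < 0 occur).

## Radar value summary

Cost axes score `100 × min(cost)/cost` (cheapest strategy = 100, reciprocal
so "farther out is better" holds on every axis); outcome rates score as
percentages; QALYs scale by `100/horizon-years` (full health throughout the
horizon = 100; the reference chart does not state its QALY mapping, so only
relative comparisons are meaningful). Spoke order is fixed by configuration
and shared across strategies; the polygon area `½ sin(2π/n) Σ rᵢrᵢ₊₁` is
the headline comparator. Conservative care has no endovascular procedure,
so its procedural-success axis is set to 100%.

## Synthetic data

The generators define the study conditions for all tests: fixture logs
reproducing the published cost tables exactly (including the 1.5 × EUR 1420
stent line, 55% of goods costs, and the IVUS line at 18%); per-patient
lognormal perturbations of minutes and goods costs with unit mean
(CV 0.2 by default, emulating case-mix variability such as patient weight
and complexity) so sample means converge to the fixture roll-up; and
simulated study pools drawing study-level proportions on the arcsine scale
(SD `τ` around the transform of the true proportion) with binomial event
counts. What they do not emulate: correlated step durations within a
patient, payer-mix differences between centres, or time trends — so passing
moment tests show unbiasedness of the roll-up under independent noise, not
robustness to structured real-world variation.

## Numerical choices and limitations

- Currency: floats internally, half-up rounding to the cent only at
  reporting (`decimal`-based; Python's builtin `round` is banker's).
- Recurrence calibration: Brent with `xtol = 1e-12`; infeasible targets
  (recurrence unreachable by the horizon) raise rather than clip.
- Occupancy conservation is asserted at 1e-12 every run.
- The reference model's exact transition structure is unpublished; base-case
  QALYs and costs are treated as diagnostic calibration targets (tracked
  within 5%, actual agreement ≈1%), and the ICUR — a ratio of two small
  differences — inherits amplified deviation (≈11.6k vs the reported
  ≈10.3k EUR/QALY from the hospital perspective). Conclusions that depend
  on the ICUR's order of magnitude and the acceptability threshold
  (≈EUR 10–12k/QALY) are insensitive to this.
- The `constant_hazard` healing alternative is structurally different (it
  keeps healing beyond the mean time), and its outcomes deviate far from
  the reference means; it is provided for structure-sensitivity analysis,
  not as a calibrated base case.
- Simulation sizes in the test suite (200 replicates × 20 studies for
  recovery, 1000 PSA draws, 2000 noisy patient logs) were chosen as the
  smallest sizes at which the Monte-Carlo standard errors are comfortably
  below the asserted tolerances.
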