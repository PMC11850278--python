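# Methods

This note documents the model implemented in `vatfood`: its assumptions, the
parameters that matter, the synthetic data it is tested on, and the numerical
choices made where the design was genuinely open.

## Scenario and price mechanism

A VAT schedule holds one rate per food group (fractions, e.g. 0.21) plus the
country's maximum rate. Scenarios rewrite rates: `zero_fv` (fruits,
vegetables, legumes, nuts → 0), `max_md` (beef, lamb, pork, poultry, dairy →
maximum rate), `combo` (both), and combo variants restricted to meat or red
meat. Scenario application is idempotent and order-independent.

Tax incidence is not identified by the data the model consumes, so the
default is **100% pass-through onto a fixed tax-exclusive price**: a rate
move t → t′ changes the consumer price by (1 + t + φ(t′−t))/(1+t) − 1 with
φ = 1. φ is configurable per scenario. Because "price change" is reported
in two conventions in the policy literature, the results table emits both
the percentage-point change in the rate (`d_vat_*_pp`) and the relative
consumer-price change (`d_price_*_pct`).

## Demand system

Demand is represented by uncompensated (Marshallian) price elasticities, so
income effects are embedded and no separate income term is needed. Priors
are calibrated to Engel aggregation (Σ wᵢηᵢ = 1) and Cournot aggregation
(Σᵢ wᵢεᵢⱼ = −wⱼ) by one of:

* **projection** (default): minimise Σ((x − x̂)/σ)² subject to the linear
  restrictions, solved exactly via the dense KKT system (σ = 1 unless
  supplied). With disjoint constraints this equals the per-column closed
  form, but the general solve also supports the optional homogeneity
  restriction (Σⱼ εᵢⱼ + ηᵢ = 0, off by default — it is not required for the
  adding-up consistency the pipeline relies on).
* **gme**: each coefficient is re-expressed as the mean of a 3-point
  distribution on supports x̂ ± 3σ with a uniform reference; cross-entropy is
  minimised subject to the same restrictions. The implementation solves the
  exact convex dual (one multiplier per restriction) by damped Newton
  iterations; infeasible supports are detected up front and reported with
  advice to widen them.

Both methods verify residuals ≤ 1e−8 post-hoc and fail loudly otherwise.

The demand update is **log-linear**, qᵢ′ = qᵢ·exp(Σⱼ εᵢⱼ Δln pⱼ): exact under
constant elasticities, aggregates cleanly over large price changes, and keeps
demand positive. The first-order linear form is available behind
`form="linear"` for comparison. Calibration is per-country; calibrated
matrices are cached on the dataset.

## Comparative risk assessment

Intake = demand × (1 − waste share). Five dietary risk factors (red meat;
fruits; vegetables; nuts; legumes) plus the BMI distribution give eight
diet- and weight-related exposures across five causes of death (CHD, stroke,
type-2 diabetes, cancer in aggregate, respiratory disease).

* Dose–response is log-linear in intake: MR = RR^(Δx/unit), with RR per
  `unit_size` g d⁻¹. Protective exposures are capped at a theoretical
  minimum-risk exposure level (TMREL) from above (no credit beyond it);
  harmful exposures are floored at theirs (no credit below it).
* The energy-intake change (waste-adjusted, kcal d⁻¹) shifts steady-state
  body weight by k·Δkcal with **k = 0.0454 kg per kcal d⁻¹**, hence mean BMI
  by k·Δkcal/height². BMI is Normal with fixed spread; only the mean shifts.
  Category prevalences (cutoffs 18.5/25/30 kg m⁻²) reweight BMI-category
  relative risks, and the BMI term is the scenario/baseline ratio of
  RR-weighted prevalences. The underweight category's RR is configurable and
  its contribution is visible through the factor attribution column.
* Per cause, the combined MR is the product of factor MRs (multiplicative
  independence); averted deaths are mortality·(1 − MR), negative values
  (added deaths) allowed. The by-cause decomposition sums to the total
  exactly; the by-factor attribution column reports each factor *alone*
  (others at baseline) and is therefore not additive — it is a diagnostic,
  not a partition.

The CRA uses population-mean exposures, not full intake distributions, and
point-estimate RRs without uncertainty intervals. The shipped RR/TMREL
configuration is **illustrative**: values are plausible in sign and
magnitude and were chosen so dietary factors (dominated by fruits and
vegetables) carry most of the mortality response and the weight channel
roughly a tenth, with TMRELs above typical European intakes as is
conventional in this framework. Study-grade analyses must supply their own
`risk_model.yaml`.

## Environment and economics

Four endpoints per kg of food: GHG (kg CO₂e), land (m²), freshwater (L),
eutrophication (g PO₄³⁻e); national totals are demand × footprint ×
population × 365, reported in Mt CO₂e, km², km³ and t PO₄³⁻e. One regional
(European) footprint set is used — footprints differ far more across food
categories than across neighbouring countries — with per-country override
possible by editing `footprints.csv`.

Producer prices are fixed across scenarios (no supply response). Diet cost
is gross-of-VAT expenditure per person-day; revenue is the tax wedge scaled
to the year; under partial pass-through the absorbed share reduces producer
receipts so the accounting identity consumer expenditure − producer receipts
= revenue always holds. Climate damages use a social cost of carbon of
US$185 per t CO₂e by default (configurable); health costs use cause-specific
cost-of-illness per death. Net benefit = Δrevenue + climate savings + health
savings, with components retained.

The carbon-price equivalence applies τ·f/1000 per kg ad valorem-equivalently
to consumer prices, propagates it through the calibrated demand system, and
bisects τ on [0, 1000] until the achieved European GHG reduction is within
0.1% (relative) of the target.

## Synthetic Europe

The generator emulates the structure of the European study setting: 28
countries × 24 food groups by default, all drawn from one seeded generator
(identical configs → byte-identical tables).

* **VAT**: country maximum rates uniform on [0.17, 0.27]; a mixture of
  zero-rate (4%), reduced-rate (82%, category-level rates between 5% and 60%
  of the maximum) and full-rate (14%) countries, mirroring the observed
  composition (about one zero-rater and four full-raters among 28). A
  "UK-like" (all food zero-rated, max 0.20) and a "DK-like" (everything at
  max 0.25) country are always present to exercise the boundary cases.
* **Demand** is log-normally jittered around European-scale means, softly
  anchored so mean M&D demand ≈ 745 g d⁻¹ and F&V ≈ 560 g d⁻¹ (±20%);
  energy densities, waste shares and prices are realistic per-group
  constants with country-level jitter. Budget shares derive from demand ×
  gross prices and sum to one by construction.
* **Elasticity priors**: own-price uniform on [−1.2, −0.2] (inelastic),
  cross-price Normal(−0.015, 0.012) — slightly negative, as the income-effect
  component of uncompensated cross elasticities implies — income uniform on
  (0.3, 1.1).
* **Footprints** are log-normally jittered around per-group medians, with
  M&D GHG rescaled so the M&D:F&V per-kg ratio equals the configured value
  (default 8).
* **Mortality** is CHD-dominant across the five causes at roughly 1% of
  population per year in total; cost-of-illness scales with GDP per capita.

What the generator does **not** emulate: real national statistics, demand
seasonality, within-country heterogeneity (age, income), correlated
elasticity structure across countries, and trade. Passing tests on this data
demonstrate internal consistency, correct mechanics and directional
behaviour of the pipeline — not calibrated magnitudes for any real country.

## Numerical choices and problem sizes

* Rates are fractions internally; percent only at I/O boundaries.
* Calibration residual tolerance 1e−8 (verified post-solve); KKT solved
  densely (n = 24 → a 625-unknown system, milliseconds).
* Producer-price adjustment computes the gross-price ratio before
  multiplying so an unchanged schedule is exactly neutral; the baseline
  scenario therefore yields bit-exact zero deltas.
* Percentage changes on a zero base are reported as 0 when the change is
  zero and NaN (flagged undefined) otherwise.
* GME Newton iterations cap at 200 with step halving; bisection for the
  carbon price caps at 200 iterations, relative tolerance 1e−3.
* Tests run the pipeline on an 8-country dataset and the directional checks
  on the full 28-country Europe; the calibration consistency check draws
  1,000 random priors with n between 2 and 24. The whole suite completes in
  a few seconds on one CPU.

## Known limitations

No supply-side or general-equilibrium response; no distributional analysis
within countries; no interaction with other taxes; single regional footprint
set; point-estimate risks; mean-exposure CRA; cancer modelled in aggregate
only; the illustrative risk configuration is for testing and demonstration,
not inference about real populations.
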