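# Methods

## The costing model

`nutricost` implements financial (budgetary) costing of nutrition-specific
intervention packages by the *program-experience* method. For every
intervention *i* in a scenario,

```
cost_i  =  UC_i  ×  TP_i  ×  coverage_i        [US$ per year]
```

with `UC_i` an observed per-beneficiary unit cost from an operating
programme, normalized to US$ per beneficiary per year, and `TP_i` the
projected number of eligible beneficiaries in the target year. Scenario
totals, category totals and percentage shares are exact sums over lines;
no discounting, multi-year phasing, economies of scale, beneficiary time
costs, or cost-effectiveness modelling is attempted — the output is a
full-coverage annual budget envelope, nothing more.

"Full coverage" means 100% of the target population, with one exception:
SAM treatment in the community-based (CMAM) model, where an 80% operational
ceiling is folded into the caseload definition because sustained coverage
above 80% is not considered attainable at scale.

## Demographic projection and cohorts

Inputs per region are census-style: a base-year population by age band and
sex, a crude birth rate (CBR, births/1000/yr) and an average annual growth
rate. We project totals by compound growth,
`P(t) = P(0)·(1+g)^t`, derive annual births as `P(t)·CBR/1000`, and size
child cohorts with a **stationary approximation**: an age window of *m*
months holds `births · m/12` children. This deliberately ignores under-five
mortality and fertility change; it overstates older child cohorts by
roughly the cumulative mortality to that age (a few percent in
contemporary India). Adolescents (11–18y) are sliced from the age-band
table with uniform interpolation inside bands; all intervals are half-open
`[lo, hi)`.

Derived cohorts and their conventions:

* `pregnant_women = births × pregnancy_multiplier` (default 1.0 — no
  pregnancy-loss adjustment; the multiplier is exposed for users who want
  one).
* `lactating_mothers_0_6m = births`: this is an *annualized beneficiary
  count* — every birth during the year opens one 6-month benefit spell —
  not the point-in-time count of mothers with an infant under six months
  (which would be births/2).
* `households_with_u5 = children_0_59m / 2` (programme norm of two
  under-fives per household).

Because the published national analysis never states its cohort formulas,
the packaged fixture carries **back-derived cohort overrides**
(`TP = printed cost / unit cost`), and overrides always take precedence
over formula values. The two are never averaged: `nutricost.synthetic.reconcile()`
reports formula-vs-fixture ratios per intervention. Notable discrepancies
surfaced there rather than hidden: the two packages imply mutually
inconsistent 12–59-month deworming cohorts (≈97.4M vs ≈118.9M), the
published adolescent line back-derives to ≈100.5M (consistent with a
girls-only programme, not all adolescents), and the child cohorts sit
~15–25% below the stationary formula values, as expected when mortality is
ignored.

## Target-population rules

Each intervention declares a `TargetRule`: source cohort, optional
prevalence filter (weight-for-age or weight-for-height Z-score threshold,
with a multiplier, e.g. incidence ≈ 2 × point prevalence of severe
wasting), incidence/inpatient multipliers, a static exclusion fraction, a
malaria-endemic-area restriction, a region-specific exclusion of
government-employed women (maternity benefit), and an optional subtraction
of another intervention's resolved target (micronutrient powders exclude
complementary-food recipients; subtraction floors at zero and is resolved
in topological order, with cycles rejected).

The two SAM caseload models:

* facility-based: `children_6_59m × prev(WHZ<−3) × 2 × 0.15` — twice the
  point prevalence for annual incidence, 15% treated as inpatients, costed
  at full coverage (the back-derived published line carries no additional
  80% factor, so the engine's default coverage for this line is 1.0 and
  the cap is left as a config knob);
* community-based (SUN): `children_6_59m × prev(WHZ<−3) × 2 × (1−0.5) × 0.8`
  — preventive interventions are assumed to halve SAM prevalence first and
  coverage is capped at 80% of the remainder, both part of the *target
  definition* in this model.

## Unit-cost normalization

Unit costs arrive per day, per visit, per household-year, per case, per
pregnancy or already per beneficiary-year. Conventions:

* feeding days: 300/yr for full-year rations, 150 for 6-month
  entitlements, 90 for the 3-month therapeutic ration;
* visit schedules: the per-visit rate times the annual visit count
  (4.1 antenatal counselling visits, 15.2 breastfeeding-counselling
  visits, 13.3 and 12.2 complementary-feeding visits);
* household rates divide by 2 children under five per household;
* exchange rate: default 62.0 INR/USD, **calibrated** so the ICDS child
  ration norm Rs 6/day × 300 days annualizes to $29.03 exactly (the rate
  is not stated in the source cost norms, only rounded per-day dollar
  figures; 62.0 reproduces every published annual cell to the cent except
  two noted below);
* inflation: a plain multiplicative factor, default 1.0 (no index or base
  year is specified by the sources; the published annual cells reproduce
  without any inflation term).

Money is rounded half-up — unit costs to the cent, cost lines to 0.01 US$
million — for reporting only; full precision is carried internally.
Registry entries may store a `printed_annual_usd`: the annual value as
published, used for costing so that published lines reproduce verbatim.
Two entries differ from our rounding path by one cent (the
pregnant/lactating ration publishes $16.93 where Rs 7 × 150/62.0 = 16.94;
one counselling rate publishes $7.47 where 0.56 × 13.3 = 7.45); the
registry keeps the published values and records the difference in its
`source` notes.

## Scenarios, fixture and back-derivation

Scenario configs are declarative TOML (`[scenario]`, `[currency]`,
`[unit_costs.*]`, `[intervention.*]` with nested `target` tables); the
SUN/India Plus differences are pure data. Category labels follow the
published comparison-figure groupings (the SUN behaviour-change programme
is grouped under counselling; fortification exists only in SUN; the
maternity cash transfer only in India Plus).

The packaged India 2014 fixture stores the published inputs — national
per-intervention cost anchors for both packages, the 35 state/UT
five-category cost anchors and total populations, and endemic-state flags
— and *back-derives* target populations as `cost × 1e6 / annual UC`.
Forward-costing the back-derived targets reproduces every printed line
exactly (the round-trip identity that anchors the test suite). Composite
published lines (counselling 6–24m, pregnant+lactating rations and IFA)
are not decomposable from the printed data; their fixture targets are
back-derived against the line's primary annual rate and should be read as
beneficiary-equivalents at that rate. The India Plus line sum is 5930.92
US$M against a printed total of 5930.91 (penny rounding in the source
table); the engine documents a ±0.02 US$M reproduction tolerance. National
demographic parameters are calibrated to the fixture: growth so the 2011
census base (1210.85M) projects to the back-derived 1275.4M in 2014
(≈1.75%/yr), CBR so projected births equal the back-derived 28.19M
pregnancy cohort (≈22.1/1000), severe-wasting prevalence back-solved from
the SAM treatment line (≈6.4%), and the government-employment share from
the cash-transfer line (≈0.33%). Wasting prevalence (WHZ<−2) is not
back-derivable and is set to 0.20, the national-survey level of the
period. State records reuse the national rates and a common age-pyramid
shape scaled to published state totals — adequate for carrying the
category anchors and endemic flags, not a substitute for state-specific
vital statistics.

## Synthetic data generator

`generate_regions` draws region tables that emulate the *spread* of Indian
states: totals uniform on 0.1–200 million, CBR 14–28/1000, growth
0.5–2.5%/yr, wasting 8–28%, severe wasting 2–10% (redrawn by rejection
until ≤ wasting), severe underweight 5–18%, government-employment share
0–8%, endemic flag with probability 0.34 (12 of 35 states are endemic).
Age structure is a fixed geometric pyramid (ratio 0.9 per 5-year band,
≈11% under five) with a 51.7% male share. All draws flow through one
`numpy` Generator seeded from `GeneratorParams.seed`, so outputs are
byte-reproducible. What the generator does **not** emulate: spatial
correlation between prevalence and fertility, state-specific age
pyramids, urban/rural structure, or trends over time — so passing tests on
synthetic regions demonstrates engine correctness (invariants, linearity,
conservation, determinism), not demographic realism.

## Numerical choices and degenerate inputs

Target populations are carried as fractional persons (back-derived values
are non-integer by construction; rounding beneficiaries would break the
round-trip identity). Aggregation is plain summation in float64 — with at
most a few hundred lines, error is far below the 0.01 US$M reporting
quantum. Zero grand totals make shares undefined and raise rather than
return NaN. Empty age-band tables, gaps or non-[0,100) coverage, reversed
intervals, prevalences outside [0,1], severe > moderate wasting, growth
≤ −100%/yr, and cyclic or dangling subtraction references are all rejected
with typed errors at construction or load time.

## Known limitations

* Financial costs only; no opportunity costs, no mass-media
  behaviour-change costs, no cost-effectiveness linkage.
* Constant returns assumed — no economies of scale in unit costs.
* The stationary cohort approximation ignores under-five mortality;
  fixture overrides correct this only where a published line pins the
  cohort.
* State-level analysis is anchored to five published category totals;
  intervention-level state costs are not recoverable.
* The anthropometric prevalences behind the fixture date to a 2005–06
  national survey; wasting has likely declined since, which would shrink
  the SAM-related lines materially.
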